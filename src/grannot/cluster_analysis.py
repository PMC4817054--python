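"""Tandem gene-array detection on scaffolds.

Same-type receptor genes frequently sit in tandem arrays produced by local
duplication; an array is a maximal run of genes on one scaffold whose
consecutive gaps do not exceed ``max_gap``. When a type filter is applied,
gaps are measured between consecutive genes *of that type*, ignoring
interleaved genes of other types — interleaving does not break an array,
which matches how mixed-type scaffolds are described in the field.
"""
from __future__ import annotations

from dataclasses import dataclass

from .bitter_typing import GRClassification

DEFAULT_MAX_GAP = 100_000
DEFAULT_MIN_ARRAY_SIZE = 3


@dataclass(frozen=True)
class TandemArray:
    scaffold_id: str
    member_gene_ids: tuple[str, ...]
    bitter_type: str  # filter applied, or "any"
    start: int
    end: int

    @property
    def size(self) -> int:
        return len(self.member_gene_ids)

    @property
    def span(self) -> int:
        return self.end - self.start


def detect_tandem_arrays(genes: list[GRClassification], max_gap: int = DEFAULT_MAX_GAP,
                         min_array_size: int = DEFAULT_MIN_ARRAY_SIZE,
                         type_filter: str | None = None) -> list[TandemArray]:
    """Chain positioned genes into maximal tandem arrays per scaffold.

    Genes are sorted by start; a chain breaks when the gap between one gene's
    end and the next gene's start exceeds ``max_gap``. Chains shorter than
    ``min_array_size`` are dropped. With ``type_filter`` only genes of that
    bitter type are chained (and gap-measured).
    """
    if max_gap <= 0 or min_array_size <= 0:
        raise ValueError("max_gap and min_array_size must be positive")
    for g in genes:
        if not g.scaffold:
            raise ValueError(f"gene {g.gene_id!r} lacks scaffold coordinates")
    pool = [g for g in genes
            if type_filter is None or g.bitter_type.value == type_filter]
    by_scaffold: dict[str, list[GRClassification]] = {}
    for g in pool:
        by_scaffold.setdefault(g.scaffold, []).append(g)

    label = type_filter or "any"
    arrays: list[TandemArray] = []
    for scaf in sorted(by_scaffold):
        members = sorted(by_scaffold[scaf], key=lambda g: (g.start, g.end, g.gene_id))
        chain: list[GRClassification] = []
        for g in members:
            if chain and g.start - chain[-1].end > max_gap:
                if len(chain) >= min_array_size:
                    arrays.append(_emit(scaf, chain, label))
                chain = []
            chain.append(g)
        if len(chain) >= min_array_size:
            arrays.append(_emit(scaf, chain, label))
    return arrays


def _emit(scaffold: str, chain: list[GRClassification], label: str) -> TandemArray:
    return TandemArray(
        scaffold_id=scaffold,
        member_gene_ids=tuple(g.gene_id for g in chain),
        bitter_type=label,
        start=min(g.start for g in chain),
        end=max(g.end for g in chain),
    )
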