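"""Structural typing of bitter receptors.

Bitter GRs fall into three structural classes: Type 1 genes contain introns
(3-4 exons) and encode roughly 400 residues; Type 2 genes are long intronless
genes (>400 aa); Type 3 genes are short intronless genes (200-350 aa, sharp
bound <360 aa). Intronless lengths in [360, 400] or below 200 are not covered
by the definitions and are reported as unknown. Pseudogenes (internal stop in
the ORF) and partial models (missing terminus) are flagged and excluded from
the typed counts, mirroring how repertoire summary tables keep a separate
pseudogene column and an unknown column.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .genome_io import GeneModel

TYPE2_MIN_LENGTH = 400   # exclusive: intronless and > 400 aa
TYPE3_MAX_LENGTH = 360   # exclusive: intronless and < 360 aa
TYPE3_MIN_LENGTH = 200   # inclusive lower bound of the short class


class Partial(str, Enum):
    NONE = "none"
    MISSING_N = "missing_n"
    MISSING_C = "missing_c"
    MISSING_BOTH = "missing_both"


class BitterType(str, Enum):
    TYPE1 = "type1"
    TYPE2 = "type2"
    TYPE3 = "type3"
    UNKNOWN = "unknown"
    NOT_BITTER = "not_bitter"


def detect_pseudogene(gm: GeneModel) -> bool:
    """True iff an in-frame stop occurs before the final codon.

    Codons containing N never call a stop (they translate to X upstream), so
    assembly gaps cannot create pseudogene calls.
    """
    return gm.internal_stop


def detect_partial(protein: str, has_terminal_stop: bool,
                   require_start_met: bool = True,
                   min_complete_length: int = 100) -> Partial:
    """Flag gene models missing a terminus.

    missing_n: first residue is not methionine (when ``require_start_met``);
    missing_c: the CDS lacked a terminal stop codon. Proteins shorter than
    ``min_complete_length`` are flagged missing_both (fragments).
    """
    if not protein:
        raise ValueError("empty protein")
    missing_n = require_start_met and not protein.startswith("M")
    missing_c = not has_terminal_stop
    if len(protein) < min_complete_length:
        return Partial.MISSING_BOTH
    if missing_n and missing_c:
        return Partial.MISSING_BOTH
    if missing_n:
        return Partial.MISSING_N
    if missing_c:
        return Partial.MISSING_C
    return Partial.NONE


def classify_bitter_type(subfamily: str, length_aa: int, exon_count: int,
                         pseudogene: bool, partial: Partial,
                         type2_min_length: int = TYPE2_MIN_LENGTH,
                         type3_max_length: int = TYPE3_MAX_LENGTH,
                         type3_min_length: int = TYPE3_MIN_LENGTH) -> BitterType:
    """Type a bitter receptor by intron status and polypeptide length.

    Pseudogenes are typed unknown here and counted in their own column by the
    summary; partial models are never length-typed. Intron-containing genes
    are Type 1 irrespective of length; intronless genes are Type 2 above
    ``type2_min_length`` and Type 3 in [``type3_min_length``,
    ``type3_max_length``); the leftover intronless bands map to unknown.
    """
    if subfamily != "bitter":
        raise ValueError(f"classify_bitter_type called on non-bitter gene ({subfamily!r})")
    if pseudogene or partial is not Partial.NONE:
        return BitterType.UNKNOWN
    if exon_count >= 2:
        return BitterType.TYPE1
    if length_aa > type2_min_length:
        return BitterType.TYPE2
    if type3_min_length <= length_aa < type3_max_length:
        return BitterType.TYPE3
    return BitterType.UNKNOWN


@dataclass(frozen=True)
class GRClassification:
    gene_id: str
    subfamily: str
    bitter_type: BitterType
    length_aa: int
    exon_count: int
    pseudogene: bool
    partial: Partial
    scaffold: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"


def classify_gene(gm: GeneModel, subfamily: str, **thresholds) -> GRClassification:
    pseudo = detect_pseudogene(gm)
    partial = detect_partial(gm.protein, gm.has_terminal_stop)
    if subfamily == "bitter":
        btype = classify_bitter_type(
            subfamily, gm.length_aa, gm.exon_count, pseudo, partial, **thresholds
        )
    else:
        btype = BitterType.NOT_BITTER
    return GRClassification(
        gene_id=gm.gene_id, subfamily=subfamily, bitter_type=btype,
        length_aa=gm.length_aa, exon_count=gm.exon_count,
        pseudogene=pseudo, partial=partial,
        scaffold=gm.scaffold_id, start=gm.start, end=gm.end, strand=gm.strand,
    )


@dataclass
class RepertoireSummary:
    """Per-gene classification table plus a one-row family summary.

    The summary row follows the usual repertoire-table layout: subfamily
    counts, a separate pseudogene column, the bitter-clade size, the typed
    bitter total (clade minus pseudogenes, the number the per-type columns
    partition), per-type counts and an unknown column for non-pseudogene
    bitter genes that could not be typed. ``partial_flagged`` reports the raw
    partial-flag count, which need not equal the unknown column.
    """

    per_gene: pd.DataFrame
    table: pd.DataFrame

    @property
    def counts(self) -> dict[str, int]:
        return {k: int(v) for k, v in self.table.iloc[0].items() if k != "assembly"}


def summarize_repertoire(classifications: list[GRClassification],
                         assembly: str = "assembly") -> RepertoireSummary:
    """Tabulate a classified repertoire.

    Invariants enforced: subfamily counts sum to the total; type1 + type2 +
    type3 + unknown equals bitter total minus pseudogene count.
    """
    ids = [c.gene_id for c in classifications]
    if len(set(ids)) != len(ids):
        dup = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate gene ids in repertoire: {dup}")

    per_gene = pd.DataFrame(
        {
            "gene_id": ids,
            "scaffold": [c.scaffold for c in classifications],
            "start": [c.start for c in classifications],
            "end": [c.end for c in classifications],
            "strand": [c.strand for c in classifications],
            "subfamily": [c.subfamily for c in classifications],
            "bitter_type": [c.bitter_type.value for c in classifications],
            "length_aa": [c.length_aa for c in classifications],
            "exon_count": [c.exon_count for c in classifications],
            "pseudogene": [c.pseudogene for c in classifications],
            "partial": [c.partial.value for c in classifications],
        }
    ).sort_values("gene_id", kind="stable").reset_index(drop=True)

    bitter = [c for c in classifications if c.subfamily == "bitter"]
    pseudo = sum(c.pseudogene for c in bitter)
    typed = {t: sum(1 for c in bitter if not c.pseudogene and c.bitter_type is t)
             for t in (BitterType.TYPE1, BitterType.TYPE2, BitterType.TYPE3,
                       BitterType.UNKNOWN)}
    row = {
        "assembly": assembly,
        "total": len(classifications),
        "co2": sum(c.subfamily == "co2" for c in classifications),
        "sugar": sum(c.subfamily == "sugar" for c in classifications),
        "gr43a_like": sum(c.subfamily == "gr43a_like" for c in classifications),
        "pseudo": pseudo,
        "bitter_clade": len(bitter),
        "bitter_total": len(bitter) - pseudo,  # the typed-bitter column
        "type1": typed[BitterType.TYPE1],
        "type2": typed[BitterType.TYPE2],
        "type3": typed[BitterType.TYPE3],
        "unknown": typed[BitterType.UNKNOWN],
        "partial_flagged": sum(c.partial is not Partial.NONE for c in classifications),
    }
    assert row["co2"] + row["sugar"] + row["gr43a_like"] + row["bitter_clade"] == row["total"]
    assert row["type1"] + row["type2"] + row["type3"] + row["unknown"] == row["bitter_total"]
    return RepertoireSummary(per_gene, pd.DataFrame([row]))
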