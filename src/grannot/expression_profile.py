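"""Presence/absence expression profiling from read-count tables.

Receptor genes are expressed at very low levels, and with single (unreplicated)
libraries per tissue, between-library level comparisons are not meaningful;
the profile therefore reduces to a conservative detected / not-detected call
per gene per library: a length- and depth-normalised relative abundance
(RPKM) thresholded at a uniform cutoff.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DEFAULT_CUTOFF_RPKM = 1.0


@dataclass
class ExpressionMatrix:
    """Raw counts (genes x libraries) with gene lengths (bases) and library
    sizes (total mapped reads)."""

    counts: pd.DataFrame
    gene_lengths: pd.Series
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype("int64")
        if (self.counts < 0).any().any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.index) - set(self.gene_lengths.index)
        if missing:
            raise ValueError(f"genes without lengths: {sorted(missing)[:5]}")
        missing = set(self.counts.columns) - set(self.library_sizes.index)
        if missing:
            raise ValueError(f"libraries without sizes: {sorted(missing)[:5]}")
        self.gene_lengths = self.gene_lengths.loc[self.counts.index]
        self.library_sizes = self.library_sizes.loc[self.counts.columns]
        if (self.gene_lengths <= 0).any():
            bad = self.gene_lengths[self.gene_lengths <= 0].index.tolist()
            raise ValueError(f"zero-length genes: {bad[:5]}")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        short = self.library_sizes < self.counts.sum(axis=0)
        if short.any():
            raise ValueError(
                f"library sizes smaller than column sums: {short[short].index.tolist()[:5]}"
            )


def relative_abundance(em: ExpressionMatrix) -> pd.DataFrame:
    """RPKM: counts / (gene length in kb x library size in millions)."""
    kb = em.gene_lengths / 1_000.0
    millions = em.library_sizes / 1_000_000.0
    return em.counts.div(kb, axis=0).div(millions, axis=1)


def call_presence(abundance: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF_RPKM,
                  ) -> pd.DataFrame:
    """Boolean detected matrix: abundance >= cutoff, applied uniformly."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if cutoff == 0:
        return abundance > 0  # any mapped read counts as detected
    return abundance >= cutoff


@dataclass
class PresenceSummary:
    per_group_detected: pd.Series   # group -> number of genes detected in >=1 member library
    gene_breadth: pd.Series         # gene -> number of libraries where detected
    detected_total: int             # genes detected anywhere


def presence_summary(presence: pd.DataFrame,
                     library_groups: dict[str, list[str]]) -> PresenceSummary:
    """Summarise presence calls over groups of libraries (tissues, stages).

    A gene counts as detected in a group if present in at least one member
    library; ``gene_breadth`` is the per-gene number of libraries with a
    detection. Every library must belong to a group.
    """
    grouped = [lib for libs in library_groups.values() for lib in libs]
    if len(grouped) != len(set(grouped)):
        raise ValueError("library groups overlap")
    orphans = set(presence.columns) - set(grouped)
    if orphans:
        raise ValueError(f"libraries in no group: {sorted(orphans)}")
    per_group = pd.Series(
        {g: int(presence[libs].any(axis=1).sum()) for g, libs in library_groups.items()},
        name="detected",
    )
    breadth = presence.sum(axis=1).astype("int64").rename("breadth")
    return PresenceSummary(per_group, breadth, int(presence.any(axis=1).sum()))


def read_counts_tsv(counts_path, gene_lengths_path, library_sizes_path) -> ExpressionMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(gene_lengths_path, sep="\t", index_col=0).iloc[:, 0]
    sizes = pd.read_csv(library_sizes_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionMatrix(counts, lengths, sizes)
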