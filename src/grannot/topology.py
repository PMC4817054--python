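"""Transmembrane topology prediction from hydropathy.

A Kyte-Doolittle sliding-window scanner marks candidate membrane-spanning
segments as runs of windowed mean hydropathy above a threshold; the
N-terminus side is set by the positive-inside rule (the terminus-adjacent
loop richer in K/R faces the cytoplasm) and the C-terminus side follows from
parity: an odd number of crossings puts the termini on opposite sides, an
even number on the same side. A small parameter-grid consensus stands in for
running several external predictors and comparing them.

Note the windowed track shrinks an above-threshold run relative to the
physical helix: a window must be more than half inside the helix before the
mean crosses a typical threshold, so a 21-residue helix under a 19-residue
window yields a run of roughly 13 positions. ``min_tm_len`` therefore
defaults to 9 track positions, not to a physical helix length.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from statistics import median_low

import numpy as np

from .genome_io import ProteinRecord

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}
# unknown/ambiguous residues are treated as hydropathy-neutral
_KD_DEFAULT = 0.0

DEFAULT_WINDOW = 19
DEFAULT_THRESHOLD = 1.6
DEFAULT_MIN_TM_LEN = 9
DEFAULT_MERGE_GAP = 4
CONSENSUS_WINDOWS = (15, 19, 21)

INSIDE = "inside"
OUTSIDE = "outside"
NA = "n/a"  # no membrane segments: sidedness undefined


@dataclass(frozen=True)
class TopologyPrediction:
    protein_id: str
    tm_segments: tuple[tuple[int, int], ...]  # residue intervals, 0-based half-open
    n_terminus: str
    c_terminus: str
    window: int = DEFAULT_WINDOW
    votes: tuple[int, ...] = ()

    @property
    def tmd_count(self) -> int:
        return len(self.tm_segments)


def hydropathy_profile(protein: ProteinRecord, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Windowed mean Kyte-Doolittle hydropathy, one score per residue.

    The window is centred; positions within half a window of either end use
    the truncated window that fits. ``window`` must be odd and in [7, 25].
    """
    if window % 2 == 0 or not 7 <= window <= 25:
        raise ValueError("window must be odd and within [7, 25]")
    n = len(protein.sequence)
    if n < window:
        raise ValueError(
            f"protein {protein.id!r} (length {n}) shorter than window {window}; "
            "use a smaller window"
        )
    kd = np.array([KYTE_DOOLITTLE.get(aa, _KD_DEFAULT) for aa in protein.sequence])
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(kd)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def predict_topology(protein: ProteinRecord, window: int = DEFAULT_WINDOW,
                     threshold: float = DEFAULT_THRESHOLD,
                     min_tm_len: int = DEFAULT_MIN_TM_LEN,
                     merge_gap: int = DEFAULT_MERGE_GAP) -> TopologyPrediction:
    """Predict TM segments and termini sidedness for one protein."""
    if min(threshold, min_tm_len, merge_gap) <= 0:
        raise ValueError("threshold, min_tm_len and merge_gap must be positive")
    track = hydropathy_profile(protein, window)
    segments = _segments_from_track(track, threshold, min_tm_len, merge_gap)
    n_term, c_term = _termini(protein.sequence, segments)
    return TopologyPrediction(protein.id, tuple(segments), n_term, c_term, window)


def _segments_from_track(track: np.ndarray, threshold: float, min_tm_len: int,
                         merge_gap: int) -> list[tuple[int, int]]:
    above = track >= threshold
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(above)))
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    return [r for r in merged if r[1] - r[0] >= min_tm_len]


def _kr_count(seq: str) -> int:
    return seq.count("K") + seq.count("R")


def _termini(sequence: str, segments: list[tuple[int, int]]) -> tuple[str, str]:
    if not segments:
        return NA, NA
    n_loop = sequence[: segments[0][0]]
    c_loop = sequence[segments[-1][1]:]
    even = len(segments) % 2 == 0
    kr_n, kr_c = _kr_count(n_loop), _kr_count(c_loop)
    # positive-inside: the terminus-adjacent loop richer in K/R is cytoplasmic;
    # on a tie, fall back to the aggregate rule over alternating loops
    if kr_n > kr_c:
        n_term = INSIDE
    elif kr_c > kr_n:
        c_term = INSIDE
        return (INSIDE if even else OUTSIDE), c_term
    else:
        loops = _loops(sequence, segments)
        n_side = sum(_kr_count(s) for s in loops[0::2])
        other = sum(_kr_count(s) for s in loops[1::2])
        n_term = INSIDE if n_side >= other else OUTSIDE
    c_term = n_term if even else _flip(n_term)
    return n_term, c_term


def _loops(sequence: str, segments: list[tuple[int, int]]) -> list[str]:
    bounds = [0] + [b for seg in segments for b in seg] + [len(sequence)]
    return [sequence[bounds[i] : bounds[i + 1]] for i in range(0, len(bounds) - 1, 2)]


def _flip(side: str) -> str:
    return OUTSIDE if side == INSIDE else INSIDE


def consensus_topology(predictions: list[TopologyPrediction]) -> TopologyPrediction:
    """Combine predictions over a parameter grid.

    The consensus TMD count is the median of the votes (ties round down);
    segments come from the first parameterization achieving it; termini are
    decided by majority vote with the C-terminus repaired to respect parity.
    """
    if not predictions:
        raise ValueError("no predictions to combine")
    votes = [p.tmd_count for p in predictions]
    count = median_low(sorted(votes))
    chosen = next(p for p in predictions if p.tmd_count == count)
    n_votes = [p.n_terminus for p in predictions if p.n_terminus != NA]
    if not n_votes or count == 0:
        return replace(chosen, votes=tuple(votes))
    n_term = INSIDE if n_votes.count(INSIDE) >= n_votes.count(OUTSIDE) else OUTSIDE
    c_term = n_term if count % 2 == 0 else _flip(n_term)
    return replace(chosen, n_terminus=n_term, c_terminus=c_term, votes=tuple(votes))


def predict_consensus(protein: ProteinRecord,
                      windows: tuple[int, ...] = CONSENSUS_WINDOWS,
                      threshold: float = DEFAULT_THRESHOLD,
                      min_tm_len: int = DEFAULT_MIN_TM_LEN,
                      merge_gap: int = DEFAULT_MERGE_GAP) -> TopologyPrediction:
    """Grid consensus over window sizes (windows longer than the protein are
    skipped; at least one must fit)."""
    preds = [
        predict_topology(protein, w, threshold, min_tm_len, merge_gap)
        for w in windows if len(protein.sequence) >= w
    ]
    if not preds:
        raise ValueError(f"protein {protein.id!r} shorter than every window in the grid")
    return consensus_topology(preds)
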