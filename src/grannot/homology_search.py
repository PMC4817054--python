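"""Translated homology search: six-frame scaffold translation and an
ungapped BLOSUM62 seed-and-extend scan of reference proteins against the
frames, the discovery stage that precedes manual gene-model curation.

The scan is deliberately ungapped: hits only need to flag candidate loci,
which are then refined against curated gene models downstream. Intron-sized
gaps between hits are absorbed when HSPs are merged into loci.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .genome_io import ProteinRecord, Scaffold

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM.alphabet)  # includes B, Z, X and *
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}
_STOP_SCORE = -10_000.0  # extension can never profitably cross a stop

QUERY_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
# residues outside the 20-letter alphabet (U, ambiguity codes) map to X


def _score_matrix() -> np.ndarray:
    m = np.array(_BLOSUM, dtype=float)
    x = _AA_INDEX["X"]
    m[x, :] = 0.0
    m[:, x] = 0.0
    stop = _AA_INDEX["*"]
    m[stop, :] = _STOP_SCORE
    m[:, stop] = _STOP_SCORE
    return m


_M = _score_matrix()


def _encode(peptide: str) -> np.ndarray:
    x = _AA_INDEX["X"]
    return np.fromiter((_AA_INDEX.get(aa, x) for aa in peptide), dtype=np.int64,
                       count=len(peptide))


@dataclass(frozen=True)
class TranslatedFrame:
    """One of six reading frames of a scaffold, with stops kept as '*'.

    Frames +1..+3 read the forward strand at offsets 0..2; -1..-3 read the
    reverse complement at offsets 0..2. ``genomic_span`` maps a half-open
    peptide interval back to the half-open genomic interval its codons occupy.
    """

    scaffold_id: str
    frame: int
    peptide: str
    scaffold_length: int

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"

    @property
    def offset(self) -> int:
        return abs(self.frame) - 1

    def genomic_span(self, pep_start: int, pep_end: int) -> tuple[int, int]:
        o = self.offset
        if self.frame > 0:
            return o + 3 * pep_start, o + 3 * pep_end
        L = self.scaffold_length
        return L - o - 3 * pep_end, L - o - 3 * pep_start


def six_frame_translate(scaffold: Scaffold) -> list[TranslatedFrame]:
    """Translate a scaffold in all six frames (empty peptides if length < 3)."""
    frames: list[TranslatedFrame] = []
    fwd = scaffold.sequence
    rev = str(Seq(fwd).reverse_complement())
    for sign, seq in ((1, fwd), (-1, rev)):
        for off in range(3):
            usable = max(0, (len(seq) - off) // 3) * 3
            pep = str(Seq(seq[off : off + usable]).translate()) if usable else ""
            frames.append(TranslatedFrame(scaffold.id, sign * (off + 1), pep, len(seq)))
    return frames


@dataclass(frozen=True)
class HSP:
    """An ungapped high-scoring segment pair between a query protein and a
    translated frame. Spans are 0-based half-open; ``subject_span`` is in
    frame peptide coordinates, ``genomic_span`` in scaffold bases."""

    query_id: str
    scaffold_id: str
    frame: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    genomic_span: tuple[int, int]
    score: float
    identities: int

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"


@dataclass(frozen=True)
class SearchParams:
    word_size: int = 3
    seed_threshold: float = 11.0
    x_drop: float = 20.0
    min_score: float = 50.0

    def __post_init__(self) -> None:
        if min(self.word_size, self.seed_threshold, self.x_drop, self.min_score) <= 0:
            raise ValueError("search parameters must be positive")


def _extend_on_diagonal(diag: np.ndarray, seed_start: int, word: int,
                        x_drop: float) -> tuple[int, int, float]:
    """Two-sided ungapped X-drop extension of a word hit along one diagonal.

    Returns (start, end, score) of the best-scoring segment containing the
    seed word, in diagonal coordinates.
    """
    lo, hi = seed_start, seed_start + word
    score = float(diag[lo:hi].sum())
    # extend right
    best, cur, best_hi = score, score, hi
    j = hi
    while j < len(diag):
        cur += diag[j]
        j += 1
        if cur > best:
            best, best_hi = cur, j
        elif cur < best - x_drop:
            break
    # extend left
    cur, best_lo = best, lo
    i = lo
    while i > 0:
        i -= 1
        cur += diag[i]
        if cur > best:
            best, best_lo = cur, i
        elif cur < best - x_drop:
            break
    return best_lo, best_hi, best


def search_translated(query: ProteinRecord, frames: list[TranslatedFrame],
                      params: SearchParams = SearchParams()) -> list[HSP]:
    """Scan a query protein against six translated frames.

    Word hits of ``word_size`` scoring >= ``seed_threshold`` under BLOSUM62
    are extended without gaps in both directions with X-drop termination;
    segments scoring >= ``min_score`` are reported. Stops in the subject score
    so poorly that extension never crosses them, and seeds containing a stop
    are discarded. Deterministic: results sorted by descending score, then by
    (scaffold, frame, spans).
    """
    bad = set(query.sequence) - QUERY_ALPHABET - set("XBZU")
    if bad:
        raise ValueError(f"query {query.id!r} contains invalid residues {sorted(bad)}")
    q = _encode(query.sequence)
    w = params.word_size
    hsps: list[HSP] = []
    for fr in frames:
        if len(fr.peptide) < w or len(q) < w:
            continue
        s = _encode(fr.peptide)
        S = _M[q[:, None], s[None, :]]
        # word scores on each diagonal
        W = S[: len(q) - w + 1, : len(s) - w + 1].copy()
        for k in range(1, w):
            W += S[k : len(q) - w + 1 + k, k : len(s) - w + 1 + k]
        seed_qi, seed_sj = np.nonzero(W >= params.seed_threshold)
        if seed_qi.size == 0:
            continue
        seen_segments: set[tuple[int, int, int]] = set()
        for qi, sj in zip(seed_qi.tolist(), seed_sj.tolist()):
            d = sj - qi
            diag = np.diagonal(S, offset=d)
            # np.diagonal index k maps to (k, k+d) for d>=0 and (k-d, k) for d<0
            pos = qi if d >= 0 else sj
            lo, hi, score = _extend_on_diagonal(diag, pos, w, params.x_drop)
            if score < params.min_score:
                continue
            if d >= 0:
                q0, s0 = lo, lo + d
            else:
                q0, s0 = lo - d, lo
            key = (d, lo, hi)
            if key in seen_segments:
                continue
            seen_segments.add(key)
            q1, s1 = q0 + (hi - lo), s0 + (hi - lo)
            ident = int(np.sum(q[q0:q1] == s[s0:s1]))
            hsps.append(HSP(
                query_id=query.id,
                scaffold_id=fr.scaffold_id,
                frame=fr.frame,
                query_span=(q0, q1),
                subject_span=(s0, s1),
                genomic_span=fr.genomic_span(s0, s1),
                score=score,
                identities=ident,
            ))
    hsps.sort(key=lambda h: (-h.score, h.scaffold_id, h.frame, h.query_span, h.subject_span))
    return hsps


@dataclass
class CandidateLocus:
    """A candidate gene locus: same-scaffold, same-strand HSPs whose genomic
    gaps are at most ``max_gap`` (gaps accommodate introns)."""

    scaffold_id: str
    strand: str
    genomic_span: tuple[int, int]
    supporting_hsps: list[HSP] = field(default_factory=list)

    @property
    def best_query(self) -> str:
        return max(self.supporting_hsps, key=lambda h: h.score).query_id


def merge_hsps_to_loci(hsps: list[HSP], max_gap: int = 10_000) -> list[CandidateLocus]:
    """Chain HSPs into maximal disjoint loci per (scaffold, strand)."""
    groups: dict[tuple[str, str], list[HSP]] = defaultdict(list)
    for h in hsps:
        groups[(h.scaffold_id, h.strand)].append(h)
    loci: list[CandidateLocus] = []
    for (scaf, strand), group in sorted(groups.items()):
        group.sort(key=lambda h: h.genomic_span)
        current: list[HSP] = []
        end = -1
        for h in group:
            s, e = h.genomic_span
            if current and s - end > max_gap:
                loci.append(_make_locus(scaf, strand, current))
                current = []
            current.append(h)
            end = max(end, e)
        if current:
            loci.append(_make_locus(scaf, strand, current))
    return loci


def _make_locus(scaffold_id: str, strand: str, hsps: list[HSP]) -> CandidateLocus:
    start = min(h.genomic_span[0] for h in hsps)
    end = max(h.genomic_span[1] for h in hsps)
    return CandidateLocus(scaffold_id, strand, (start, end), list(hsps))
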