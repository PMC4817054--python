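import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from grannot import homology_search as hs
from grannot.genome_io import ProteinRecord, Scaffold

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum(a, b):
    return float(BLOSUM62[a][b])


class TestSixFrameTranslate:
    def test_plus_and_minus_frame_one(self):
        frames = {f.frame: f.peptide for f in hs.six_frame_translate(Scaffold("s", "ATGAAA"))}
        assert frames[1] == "MK"
        assert frames[-1] == "FH"  # revcomp TTTCAT

    def test_offset_frames(self):
        frames = {f.frame: f.peptide for f in hs.six_frame_translate(Scaffold("s", "AATGAAA"))}
        assert frames[2] == "MK"

    def test_degenerate_short_scaffold(self):
        assert all(f.peptide == "" for f in hs.six_frame_translate(Scaffold("s", "AC")))

    def test_stops_retained(self):
        frames = {f.frame: f.peptide for f in hs.six_frame_translate(Scaffold("s", "ATGTAAAAA"))}
        assert frames[1] == "M*K"

    def test_peptide_lengths(self):
        scaf = Scaffold("s", "ACGTACGTACG")  # length 11
        for f in hs.six_frame_translate(scaf):
            assert len(f.peptide) == (11 - f.offset) // 3

    def test_genomic_span_maps_back_to_codons(self):
        scaf = Scaffold("s", "AAATGCATGAAATTT")
        for f in hs.six_frame_translate(scaf):
            for i in range(len(f.peptide)):
                g0, g1 = f.genomic_span(i, i + 1)
                codon = scaf.sequence[g0:g1]
                if f.strand == "-":
                    codon = str(Seq(codon).reverse_complement())
                assert str(Seq(codon).translate()) == f.peptide[i]


def _frames_for(peptide_dna: str) -> list[hs.TranslatedFrame]:
    return hs.six_frame_translate(Scaffold("s", peptide_dna))


def back_translate_simple(protein: str) -> str:
    """One fixed codon per residue (enough to plant exact windows)."""
    table = {
        "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
        "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
        "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
        "Y": "TAT", "V": "GTT",
    }
    return "".join(table[aa] for aa in protein)


class TestSearchTranslated:
    def test_identical_window_scores_blosum_diagonal_sum(self):
        window = "MKWYCHRDEF"
        frames = _frames_for(back_translate_simple("GGG" + window + "GGG"))
        query = ProteinRecord("q", window)
        hsps = hs.search_translated(query, frames, hs.SearchParams(min_score=30))
        assert hsps, "expected a hit on the implanted window"
        expected = sum(blosum(aa, aa) for aa in window)
        best = hsps[0]
        assert best.score >= expected
        # re-sum matrix entries over the reported span (independent oracle)
        frame = next(f for f in frames if f.frame == best.frame)
        resum = sum(
            blosum(query.sequence[qi], frame.peptide[sj])
            for qi, sj in zip(range(*best.query_span), range(*best.subject_span))
        )
        assert best.score == pytest.approx(resum)

    def test_no_seed_no_hsp(self):
        # max word score A-vs-W is below the default seed threshold
        assert 3 * blosum("A", "W") < 11
        frames = _frames_for(back_translate_simple("W" * 10))
        hsps = hs.search_translated(ProteinRecord("q", "A" * 10), frames,
                                    hs.SearchParams(min_score=1))
        assert hsps == []

    def test_single_substitution_drops_score_by_matrix_delta(self):
        window = "MKWYCHRDEF"
        mutated = "MKWYCARDEF"  # H -> A at position 5
        frames = _frames_for(back_translate_simple("GGG" + mutated + "GGG"))
        params = hs.SearchParams(min_score=20)
        hsps = hs.search_translated(ProteinRecord("q", window), frames, params)
        full = sum(blosum(aa, aa) for aa in window)
        drop = blosum("H", "H") - blosum("H", "A")
        assert any(h.score == pytest.approx(full - drop) for h in hsps)

    def test_invalid_query_characters_rejected(self):
        frames = _frames_for("ATGAAAATG")
        with pytest.raises(ValueError, match="q"):
            hs.search_translated(ProteinRecord("q", "MK1"), frames)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(11)
        dna = "".join(rng.choice(list("ACGT"), size=900))
        query_src = str(Seq(dna[300:390]).translate()).replace("*", "S")
        query = ProteinRecord("q", query_src)
        params = hs.SearchParams(min_score=40)
        fwd = hs.search_translated(query, hs.six_frame_translate(Scaffold("s", dna)), params)
        rc = str(Seq(dna).reverse_complement())
        rev = hs.search_translated(query, hs.six_frame_translate(Scaffold("s", rc)), params)
        assert sorted(h.score for h in fwd) == sorted(h.score for h in rev)
        L = len(dna)
        fwd_spans = sorted((L - e, L - s) for h in fwd for s, e in [h.genomic_span])
        rev_spans = sorted(h.genomic_span for h in rev)
        assert fwd_spans == rev_spans

    def test_min_score_monotonicity(self):
        rng = np.random.default_rng(5)
        dna = "".join(rng.choice(list("ACGT"), size=1200))
        query = ProteinRecord("q", str(Seq(dna[120:300]).translate()).replace("*", "A"))
        frames = hs.six_frame_translate(Scaffold("s", dna))
        low = hs.search_translated(query, frames, hs.SearchParams(min_score=30))
        high = hs.search_translated(query, frames, hs.SearchParams(min_score=60))
        low_keys = {(h.frame, h.query_span, h.subject_span) for h in low}
        assert all((h.frame, h.query_span, h.subject_span) in low_keys for h in high)
        assert len(high) <= len(low)


def _oracle_matrix():
    """Independent scoring matrix: BLOSUM62 with X scoring 0 and stops
    blocking extension, rebuilt from the published matrix."""
    alpha = str(BLOSUM62.alphabet)
    m = np.array(BLOSUM62, dtype=float)
    x = alpha.index("X")
    m[x, :] = 0.0
    m[:, x] = 0.0
    s = alpha.index("*")
    m[s, :] = -10_000.0
    m[:, s] = -10_000.0
    return alpha, m


def _best_segment(diag: np.ndarray) -> float:
    """Exhaustive best ungapped segment score on one diagonal (max subarray)."""
    best = -np.inf
    cur = 0.0
    for v in diag:
        cur = max(v, cur + v)
        best = max(best, cur)
    return best


class TestExhaustiveOracle:
    def test_seed_and_extend_superset_of_window_scan(self):
        """On small random scaffolds, every diagonal whose exhaustive best
        segment clears min_score and contains a word seed is reported, and
        reported scores equal matrix re-sums."""
        alpha, M = _oracle_matrix()
        idx = {aa: i for i, aa in enumerate(alpha)}
        rng = np.random.default_rng(202)
        params = hs.SearchParams(min_score=50, x_drop=20)
        for trial in range(3):
            dna = "".join(rng.choice(list("ACGT"), size=3000))
            start = int(rng.integers(0, 900)) * 3
            query_seq = str(Seq(dna[start : start + 180]).translate()).replace("*", "L")
            # sprinkle mutations so extension has to work for its score
            q = list(query_seq)
            for pos in rng.integers(0, len(q), size=6).tolist():
                q[pos] = "ARNDCEQGHILKMFPSTWYV"[int(rng.integers(20))]
            query = ProteinRecord("q", "".join(q))
            frames = hs.six_frame_translate(Scaffold("s", dna))
            hsps = hs.search_translated(query, frames, params)
            for h in hsps:
                frame = next(f for f in frames if f.frame == h.frame)
                resum = sum(
                    M[idx[query.sequence[qi]], idx[frame.peptide[sj]]]
                    for qi, sj in zip(range(*h.query_span), range(*h.subject_span))
                )
                assert h.score == pytest.approx(resum)
            reported = {}
            for h in hsps:
                d = h.subject_span[0] - h.query_span[0]
                reported[(h.frame, d)] = max(
                    reported.get((h.frame, d), -np.inf), h.score)
            for frame in frames:
                if len(frame.peptide) < 3:
                    continue
                qv = np.array([idx[c] for c in query.sequence])
                sv = np.array([idx[c] for c in frame.peptide])
                S = M[qv[:, None], sv[None, :]]
                for d in range(-len(qv) + 3, len(sv) - 2):
                    diag = np.diagonal(S, offset=d)
                    words = diag[:-2] + diag[1:-1] + diag[2:] if len(diag) >= 3 else []
                    if len(words) == 0 or np.max(words) < 11:
                        continue  # no seed: no guarantee
                    best = _best_segment(diag)
                    if best >= params.min_score:
                        assert reported.get((frame.frame, d), -np.inf) >= best


def mk_hsp(scaffold, frame, gspan, score=100.0, query="q"):
    return hs.HSP(query, scaffold, frame, (0, 10), (0, 10), gspan, score, 10)


class TestMergeLoci:
    def test_close_hsps_merge(self):
        hsps = [mk_hsp("s", 1, (1000, 1300)), mk_hsp("s", 2, (1800, 2100))]
        loci = hs.merge_hsps_to_loci(hsps, max_gap=2000)
        assert len(loci) == 1
        assert loci[0].genomic_span == (1000, 2100)

    def test_distant_hsps_split(self):
        hsps = [mk_hsp("s", 1, (1000, 1300)), mk_hsp("s", 1, (6300, 6600))]
        assert len(hs.merge_hsps_to_loci(hsps, max_gap=2000)) == 2

    def test_opposite_strands_never_merge(self):
        hsps = [mk_hsp("s", 1, (1000, 1300)), mk_hsp("s", -1, (1100, 1400))]
        loci = hs.merge_hsps_to_loci(hsps, max_gap=2000)
        assert len(loci) == 2
        assert {l.strand for l in loci} == {"+", "-"}

    def test_empty_input(self):
        assert hs.merge_hsps_to_loci([], max_gap=100) == []

    def test_max_gap_monotone_locus_count(self):
        rng = np.random.default_rng(3)
        starts = np.cumsum(rng.integers(200, 4000, size=30))
        hsps = [mk_hsp("s", 1, (int(s), int(s) + 150)) for s in starts]
        counts = [len(hs.merge_hsps_to_loci(hsps, max_gap=g))
                  for g in (100, 500, 1000, 2000, 4000)]
        assert counts == sorted(counts, reverse=True)

    def test_best_query_is_top_scorer(self):
        hsps = [mk_hsp("s", 1, (0, 100), score=60, query="low"),
                mk_hsp("s", 1, (200, 300), score=90, query="high")]
        (locus,) = hs.merge_hsps_to_loci(hsps, max_gap=1000)
        assert locus.best_query == "high"
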