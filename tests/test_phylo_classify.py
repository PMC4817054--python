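import io
import math

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj as skbio_nj

from grannot import phylo_classify as pc
from grannot.genome_io import ProteinRecord


def aln(**seqs) -> pc.Alignment:
    return pc.Alignment.from_records(
        [ProteinRecord(k, v) for k, v in seqs.items()]
    )


class TestDistances:
    def test_identical_sequences_are_zero_under_both_models(self):
        a = ProteinRecord("a", "MKWYCHRDEF" * 4)
        for model in ("p_distance", "poisson"):
            assert pc.pairwise_distance(a, ProteinRecord("b", a.sequence), model) == 0.0

    def test_single_substitution_p_distance(self):
        a = ProteinRecord("a", "MKWYCHRDEF" * 4)
        b = ProteinRecord("b", a.sequence[:5] + "A" + a.sequence[6:])
        assert pc.pairwise_distance(a, b, "p_distance") == pytest.approx(1 / 40)

    def test_poisson_closed_form_at_half(self):
        # 10 of 20 columns mismatch in a prebuilt alignment: -ln(0.5)
        al = aln(a="MKWYCHRDEFMKWYCHRDEF", b="MKWYCHRDEFAAAAAAAAAA")
        dm = pc.distance_matrix_from_alignment(al, "poisson")
        assert dm[("a", "b")] == pytest.approx(-math.log(0.5))

    def test_saturation_capped(self):
        al = aln(a="MMMMM", b="WWWWW")
        dm = pc.distance_matrix_from_alignment(al, "poisson", max_distance=7.5)
        assert dm[("a", "b")] == 7.5

    def test_pairwise_deletion_excludes_gap_columns(self):
        al = aln(a="MK--YW", b="MKCC-W")
        # comparable columns: 1, 2, 6 -> 0 mismatches
        dm = pc.distance_matrix_from_alignment(al, "p_distance")
        assert dm[("a", "b")] == 0.0

    def test_zero_comparable_columns_names_both_ids(self):
        al = aln(left="MK--", right="--CC")
        with pytest.raises(ValueError, match="left.*right"):
            pc.distance_matrix_from_alignment(al)


def dm_from(taxa, entries):
    n = len(taxa)
    d = np.zeros((n, n))
    for (i, j), v in entries.items():
        d[i, j] = d[j, i] = v
    return pc.DistanceMatrix(tuple(taxa), d)


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:2,B:3):1,(C:4,D:5)) -> additive matrix
        dm = dm_from("ABCD", {(0, 1): 5, (0, 2): 7, (0, 3): 8,
                              (1, 2): 8, (1, 3): 9, (2, 3): 9})
        tree = pc.build_nj_tree(dm)
        assert pc.tree_splits(tree) == {frozenset({"C", "D"})}
        paths = tree.tip_tip_distances()
        for i, a in enumerate("ABCD"):
            for b in "ABCD"[i + 1:]:
                assert paths[a, b] == pytest.approx(dm[(a, b)])

    def test_three_taxon_closed_form(self):
        dm = dm_from("ABC", {(0, 1): 3, (0, 2): 5, (1, 2): 6})
        tree = pc.build_nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 4.0})

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            pc.build_nj_tree(dm_from("AB", {(0, 1): 1}))

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            pc.DistanceMatrix(("a", "b", "c"), d)

    def test_equal_distance_tie_break_is_deterministic(self):
        dm = dm_from("ABCD", {(i, j): 2.0 for i in range(4) for j in range(i + 1, 4)})
        t1 = pc.build_nj_tree(dm)
        t2 = pc.build_nj_tree(dm)
        assert str(t1) == str(t2)
        tips = {t.name: t.length for t in t1.tips()}
        assert all(v == pytest.approx(tips["A"]) for v in tips.values())

    def test_random_additive_matrices_reproduced_exactly(self):
        rng = np.random.default_rng(42)
        for n in (5, 6, 7, 8):
            tree_true, taxa = random_tree(rng, n)
            dm = additive_matrix(tree_true, taxa)
            out = pc.build_nj_tree(dm)
            paths = out.tip_tip_distances()
            for i, a in enumerate(taxa):
                for b in taxa[i + 1:]:
                    assert paths[a, b] == pytest.approx(dm[(a, b)], abs=1e-9)

    def test_matches_skbio_nj_splits_on_noisy_matrix(self):
        """Independent cross-check against scikit-bio's NJ on a perturbed
        additive matrix (topology comparison)."""
        rng = np.random.default_rng(7)
        tree_true, taxa = random_tree(rng, 7)
        dm = additive_matrix(tree_true, taxa)
        d = dm.d + rng.uniform(0, 0.01, dm.d.shape)
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ours = pc.build_nj_tree(pc.DistanceMatrix(dm.taxa, d))
        theirs = skbio_nj(SkbioDM(d, ids=list(dm.taxa)))
        assert pc.tree_splits(ours) == pc.tree_splits(theirs)


def random_tree(rng, n):
    """Random unrooted topology with generic branch lengths."""
    taxa = [f"t{i}" for i in range(n)]
    nodes = [TreeNode(name=t, length=float(rng.uniform(0.5, 2.0))) for t in taxa[:3]]
    tree = TreeNode(children=nodes)
    for t in taxa[3:]:
        cands = [node for node in tree.traverse(include_self=False)]
        edge = cands[int(rng.integers(len(cands)))]
        parent = edge.parent
        half = edge.length / 2
        parent.remove(edge)
        edge.length = half
        leaf = TreeNode(name=t, length=float(rng.uniform(0.5, 2.0)))
        mid = TreeNode(children=[edge, leaf], length=half)
        parent.append(mid)
    return tree, taxa


def additive_matrix(tree, taxa):
    paths = tree.tip_tip_distances()
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = paths[taxa[i], taxa[j]]
    return pc.DistanceMatrix(tuple(taxa), d)


class TestBootstrap:
    def test_uniform_columns_give_full_support(self):
        # every column identical -> any resample reproduces the matrix
        al = aln(a="AAAAAA", b="AAAAAA"[:-1] + "A", c="CCCCCC", d="GGGGGG")
        res = pc.bootstrap_support(al, replicates=5, seed=0)
        assert res.supports and all(v == 100.0 for v in res.supports.values())

    def test_supports_bounded_and_reproducible(self):
        rng = np.random.default_rng(1)
        seqs = {f"t{i}": "".join(rng.choice(list("ACDEFGHIK"), size=40))
                for i in range(6)}
        al = aln(**seqs)
        r1 = pc.bootstrap_support(al, replicates=20, seed=9)
        r2 = pc.bootstrap_support(al, replicates=20, seed=9)
        assert r1.supports == r2.supports
        assert all(0 <= v <= 100 for v in r1.supports.values())

    def test_well_separated_clades_supported(self):
        rng = np.random.default_rng(2)
        block = 60
        seqs = {}
        for g, char in (("g1", "A"), ("g2", "Y")):
            for i in range(3):
                noise = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
                seqs[f"{g}_{i}"] = char * block + noise
        al = aln(**seqs)
        res = pc.bootstrap_support(al, replicates=100, seed=3)
        split = frozenset({"g2_0", "g2_1", "g2_2"})
        assert res.supports[split] >= 95.0

    def test_single_column_flagged_degenerate(self):
        al = aln(a="A", b="C", c="G")
        assert pc.bootstrap_support(al, replicates=2, seed=0).degenerate

    def test_replicates_must_be_positive(self):
        with pytest.raises(ValueError):
            pc.bootstrap_support(aln(a="AA", b="CC", c="GG"), replicates=0, seed=0)


def tree_of(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick), convert_underscores=False)


class TestAssignSubfamily:
    ANCHORS = {"ANC_co2_1": "co2", "ANC_co2_2": "co2", "ANC_bitter_1": "bitter",
               "ANC_bitter_2": "bitter", "ANC_bitter_3": "bitter",
               "ANC_sugar_1": "sugar"}

    def test_gene_sister_to_co2_clade(self):
        t = tree_of("((G1:1,(ANC_co2_1:1,ANC_co2_2:1):1):5,"
                    "(ANC_bitter_1:1,ANC_sugar_1:1):5,ANC_bitter_2:5);")
        a = pc.assign_subfamily(t, self.ANCHORS, "G1")
        assert a.subfamily == "co2" and not a.ambiguous
        assert set(a.anchor_support) == {"ANC_co2_1", "ANC_co2_2"}

    def test_majority_inside_bitter_clade(self):
        t = tree_of("((G1:1,ANC_bitter_1:1,ANC_bitter_2:1,ANC_bitter_3:1):1,"
                    "ANC_co2_1:1,ANC_sugar_1:1);")
        a = pc.assign_subfamily(t, self.ANCHORS, "G1")
        assert a.subfamily == "bitter" and not a.ambiguous

    def test_exact_tie_breaks_lexicographically_and_flags(self):
        t = tree_of("((G1:1,(ANC_sugar_1:1,ANC_bitter_1:1):1):1,"
                    "(ANC_co2_1:1,ANC_co2_2:1):1,ANC_bitter_2:5);")
        a = pc.assign_subfamily(t, self.ANCHORS, "G1")
        assert a.subfamily == "bitter"  # bitter < sugar
        assert a.ambiguous
        assert set(a.anchor_support) == {"ANC_sugar_1", "ANC_bitter_1"}

    def test_no_anchors_is_hard_error(self):
        t = tree_of("((G1:1,G2:1):1,G3:1,G4:1);")
        with pytest.raises(ValueError):
            pc.assign_subfamily(t, {}, "G1")

    def test_every_non_anchor_leaf_assigned_exactly_once(self):
        t = tree_of("((G1:1,(ANC_co2_1:1,ANC_co2_2:1):1):1,"
                    "(G2:1,ANC_bitter_1:1):1,(G3:1,ANC_sugar_1:1):1);")
        for g in ("G1", "G2", "G3"):
            a = pc.assign_subfamily(t, self.ANCHORS, g)
            assert a.subfamily in pc.SUBFAMILIES
            assert a.anchor_support


class TestRepertoireRecovery:
    def test_synthetic_subfamilies_recovered(self, small_repertoire, pipeline_run):
        import pandas as pd

        truth = small_repertoire.manifest.set_index("gene_id")["subfamily"]
        pred = pd.read_csv(pipeline_run / "subfamily_assignments.tsv", sep="\t"
                           ).set_index("gene_id")["subfamily"]
        accuracy = (pred.loc[truth.index] == truth).mean()
        assert accuracy >= 0.95
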