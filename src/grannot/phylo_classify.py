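"""Reference-anchored subfamily classification.

Candidate receptors are placed in a distance tree together with anchor
proteins of known subfamily (CO2, sugar, GR43a-like, bitter); each gene is
assigned the subfamily of the nearest anchored clade. Distances are
Poisson-corrected p-distances computed with pairwise deletion of gapped
columns; the tree is canonical neighbor joining with deterministic
tie-breaking. Bootstrap support resamples alignment columns.

The multiple alignment behind the distance matrix is produced by MAFFT
(single-threaded, hence deterministic); the two-sequence distance API aligns
internally with BLOSUM62 affine-gap global alignment.
"""
from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import TreeNode

from .genome_io import ProteinRecord, read_proteins, write_fasta

SUBFAMILIES = ("bitter", "co2", "gr43a_like", "sugar")  # lexicographic order

DEFAULT_MAX_DISTANCE = 10.0
_SATURATION_EPS = 1e-9


# ---------------------------------------------------------------------------
# Alignment

def _pairwise_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def pairwise_global(a: ProteinRecord, b: ProteinRecord) -> tuple[str, str]:
    """Global BLOSUM62 affine-gap alignment of two proteins (first optimum)."""
    aligner = _pairwise_aligner()
    sa = a.sequence.replace("*", "X").replace("U", "X")
    sb = b.sequence.replace("*", "X").replace("U", "X")
    aln = aligner.align(sa, sb)[0]
    return str(aln[0]), str(aln[1])


@dataclass(frozen=True)
class Alignment:
    """A multiple protein alignment as an (n taxa x L columns) character grid."""

    taxa: tuple[str, ...]
    columns: np.ndarray  # dtype '<U1', shape (n, L)

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]

    @classmethod
    def from_records(cls, records: list[ProteinRecord]) -> "Alignment":
        lengths = {len(r.sequence) for r in records}
        if len(lengths) != 1:
            raise ValueError("aligned records must all have equal length")
        grid = np.array([list(r.sequence.upper()) for r in records], dtype="<U1")
        return cls(tuple(r.id for r in records), grid)


def align_proteins(records: list[ProteinRecord], mafft_path: str | None = None) -> Alignment:
    """Multiple-align proteins with MAFFT (``--auto --thread 1``)."""
    exe = mafft_path or shutil.which("mafft")
    if exe is None:
        raise RuntimeError("mafft executable not found on PATH")
    if len(records) == 1:
        return Alignment.from_records(records)
    order = {r.id: i for i, r in enumerate(records)}
    with tempfile.TemporaryDirectory() as td:
        fa = Path(td) / "in.fasta"
        clean = [ProteinRecord(r.id, r.sequence.replace("*", "X")) for r in records]
        write_fasta(clean, fa)
        out = subprocess.run(
            [exe, "--auto", "--thread", "1", "--anysymbol", "--quiet", str(fa)],
            capture_output=True, text=True, check=True,
        ).stdout
        aln_fa = Path(td) / "out.fasta"
        aln_fa.write_text(out)
        aligned = read_proteins(aln_fa)
    aligned.sort(key=lambda r: order[r.id])
    return Alignment.from_records(aligned)


# ---------------------------------------------------------------------------
# Distances

@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (d < 0).any() or not np.isfinite(d).all():
            raise ValueError("distances must be finite and non-negative")
        object.__setattr__(self, "d", d)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.taxa.index(pair[0]), self.taxa.index(pair[1])
        return float(self.d[i, j])


def _p_to_distance(p: float, model: str, max_distance: float) -> float:
    if model == "p_distance":
        return p
    if model == "poisson":
        if p >= 1.0 - _SATURATION_EPS:
            return max_distance
        return min(-math.log(1.0 - p), max_distance)
    raise ValueError(f"unknown distance model {model!r}")


def pairwise_distance(a: ProteinRecord, b: ProteinRecord, model: str = "poisson",
                      max_distance: float = DEFAULT_MAX_DISTANCE) -> float:
    """Evolutionary distance between two proteins.

    The pair is globally aligned; columns with a gap in either sequence are
    excluded (pairwise deletion). ``p_distance`` is mismatches over compared
    columns; ``poisson`` is -ln(1-p), capped at ``max_distance`` when the
    pair is saturated.
    """
    ra, rb = pairwise_global(a, b)
    pairs = [(x, y) for x, y in zip(ra, rb) if x != "-" and y != "-"]
    if not pairs:
        raise ValueError(f"no comparable columns between {a.id!r} and {b.id!r}")
    p = sum(x != y for x, y in pairs) / len(pairs)
    return _p_to_distance(p, model, max_distance)


def distance_matrix_from_alignment(aln: Alignment, model: str = "poisson",
                                   max_distance: float = DEFAULT_MAX_DISTANCE,
                                   ) -> DistanceMatrix:
    """Pairwise-deletion distances over a multiple alignment."""
    grid = aln.columns
    n = grid.shape[0]
    valid = grid != "-"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            ncols = int(both.sum())
            if ncols == 0:
                raise ValueError(
                    f"no comparable columns between {aln.taxa[i]!r} and {aln.taxa[j]!r}"
                )
            p = float((grid[i, both] != grid[j, both]).sum()) / ncols
            d[i, j] = d[j, i] = _p_to_distance(p, model, max_distance)
    return DistanceMatrix(aln.taxa, d)


# ---------------------------------------------------------------------------
# Neighbor joining

def build_nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Canonical Saitou–Nei neighbor joining.

    Deterministic: Q-criterion ties are broken by the lexicographically
    smallest pair of cluster labels (a cluster's label is its smallest leaf
    name). Negative branch lengths are clamped to zero with the deficit moved
    to the sister edge, preserving the joined pair's summed length. For an
    additive input matrix the returned (unrooted, trifurcating-root) tree
    reproduces the matrix exactly as leaf path lengths.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    labels: list[str] = list(dm.taxa)
    D = dm.d.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        i, j = min(
            (tuple(sorted((labels[a], labels[b]))), (min(a, b), max(a, b)))
            for a, b in ties
        )[1]
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        new = TreeNode(children=[_with_length(nodes[i], li), _with_length(nodes[j], lj)])
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    # three clusters remain: closed-form three-point lengths
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = max(0.0, 0.5 * (d01 + d02 - d12))
    l1 = max(0.0, 0.5 * (d01 + d12 - d02))
    l2 = max(0.0, 0.5 * (d02 + d12 - d01))
    root = TreeNode(children=[
        _with_length(nodes[0], l0),
        _with_length(nodes[1], l1),
        _with_length(nodes[2], l2),
    ])
    return root


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def _with_length(node: TreeNode, length: float) -> TreeNode:
    node.length = float(length)
    return node


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (arbitrarily rooted) unrooted tree,
    each represented canonically as the side not containing the smallest
    leaf name."""
    taxa = frozenset(t.name for t in tree.tips())
    anchor = min(taxa)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        if anchor in side:
            side = taxa - side
        splits.add(side)
    return splits


# ---------------------------------------------------------------------------
# Bootstrap

@dataclass
class BootstrapResult:
    supports: dict[frozenset[str], float]  # split -> percent of replicates
    replicates: int
    degenerate: bool = False

    def annotate(self, tree: TreeNode) -> TreeNode:
        """Write support values (percent) onto the internal nodes of ``tree``."""
        taxa = frozenset(t.name for t in tree.tips())
        anchor = min(taxa)
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if len(side) < 2 or len(taxa - side) < 2:
                continue
            key = side if anchor not in side else taxa - side
            node.name = f"{self.supports.get(key, 0.0):.0f}"
        return tree


def bootstrap_support(aln: Alignment, replicates: int, seed: int,
                      model: str = "poisson",
                      max_distance: float = DEFAULT_MAX_DISTANCE) -> BootstrapResult:
    """Column-resampling bootstrap support for every original bipartition.

    Columns are resampled with replacement ``replicates`` times; the tree is
    rebuilt per replicate and each original split's support is the percent of
    replicate trees containing it. Reproducible given ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    original = build_nj_tree(distance_matrix_from_alignment(aln, model, max_distance))
    target_splits = tree_splits(original)
    counts = {s: 0 for s in target_splits}
    L = aln.n_columns
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        sampled = Alignment(aln.taxa, aln.columns[:, cols])
        rep_tree = build_nj_tree(distance_matrix_from_alignment(sampled, model, max_distance))
        for s in tree_splits(rep_tree):
            if s in counts:
                counts[s] += 1
    supports = {s: 100.0 * c / replicates for s, c in counts.items()}
    return BootstrapResult(supports, replicates, degenerate=(L == 1))


# ---------------------------------------------------------------------------
# Subfamily assignment

@dataclass(frozen=True)
class SubfamilyAssignment:
    gene_id: str
    subfamily: str
    anchor_support: tuple[str, ...]
    ambiguous: bool = False


def _clade_index(tree: TreeNode) -> list[frozenset[str]]:
    """Every clade of the tree read as unrooted: for each edge, both sides."""
    taxa = frozenset(t.name for t in tree.tips())
    sides: set[frozenset[str]] = set()
    for node in tree.traverse(include_self=False):
        side = frozenset([node.name]) if node.is_tip() else frozenset(
            t.name for t in node.tips())
        sides.add(side)
        sides.add(taxa - side)
    return sorted(sides, key=lambda s: (len(s), tuple(sorted(s))))


def assign_subfamily(tree: TreeNode, anchors: dict[str, str], gene_id: str,
                     clades: list[frozenset[str]] | None = None,
                     distances=None) -> SubfamilyAssignment:
    """Assign a gene the subfamily of the first anchor reached from its leaf.

    Walking outward from the gene's leaf along the tree's branches, the
    nearest anchor (smallest patristic distance) assigns its subfamily. When
    several anchors of different subfamilies tie exactly — a gene attached
    equidistantly between anchored clades — the lexicographically smallest
    subfamily wins and the assignment is flagged ambiguous, with every tied
    anchor listed in ``anchor_support``. Otherwise ``anchor_support`` lists
    the winning subfamily's anchors inside the smallest clade (in the
    unrooted sense) containing the gene and the deciding anchor.

    ``clades`` and ``distances`` may carry a precomputed
    :func:`_clade_index` / ``tree.tip_tip_distances()`` when assigning many
    genes on one tree.
    """
    if not anchors:
        raise ValueError("anchor map is empty")
    bad = set(anchors.values()) - set(SUBFAMILIES)
    if bad:
        raise ValueError(f"unknown subfamilies in anchor map: {sorted(bad)}")
    tree.find(gene_id)  # raises if absent
    anchor_ids = set(anchors) - {gene_id}
    anchor_ids &= {t.name for t in tree.tips()}
    if not anchor_ids:
        raise ValueError("tree contains no anchors")
    if distances is None:
        distances = tree.tip_tip_distances()
    dmin = min(distances[gene_id, a] for a in anchor_ids)
    tied = sorted(a for a in anchor_ids
                  if distances[gene_id, a] <= dmin + 1e-9)
    subfamilies = sorted({anchors[a] for a in tied})
    subfamily = subfamilies[0]
    ambiguous = len(subfamilies) > 1
    if ambiguous:
        return SubfamilyAssignment(gene_id, subfamily, tuple(tied), True)
    nearest = tied[0]
    if clades is None:
        clades = _clade_index(tree)
    for clade in clades:  # sorted smallest-first
        if gene_id in clade and nearest in clade:
            support = tuple(sorted(
                a for a in clade & anchor_ids if anchors[a] == subfamily))
            return SubfamilyAssignment(gene_id, subfamily, support, False)
    raise AssertionError("unreachable: every pair shares the full-tree clade")


def classify_repertoire(proteins: list[ProteinRecord], anchor_records: list[ProteinRecord],
                        anchor_map: dict[str, str], bootstrap_replicates: int = 0,
                        seed: int = 0, model: str = "poisson",
                        ) -> tuple[TreeNode, list[SubfamilyAssignment], Alignment]:
    """Align genes plus anchors, build the NJ tree and assign every gene.

    Pseudogene proteins should be supplied as their longest stop-free
    translated segment (see :func:`longest_orf_segment`).
    """
    records = list(proteins) + [r for r in anchor_records]
    aln = align_proteins(records)
    dm = distance_matrix_from_alignment(aln, model=model)
    tree = build_nj_tree(dm)
    if bootstrap_replicates:
        bootstrap_support(aln, bootstrap_replicates, seed, model).annotate(tree)
    clades = _clade_index(tree)
    distances = tree.tip_tip_distances()
    assignments = [
        assign_subfamily(tree, anchor_map, p.id, clades=clades, distances=distances)
        for p in proteins
    ]
    return tree, assignments, aln


def longest_orf_segment(protein: str) -> str:
    """Longest stop-free segment of a translated protein (pseudogene entry
    into the tree)."""
    return max(protein.split("*"), key=len)
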