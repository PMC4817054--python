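"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates a lepidopteran GR repertoire: genome scaffolds carrying
implanted receptor genes of known subfamily, bitter type, exon structure,
pseudogene/partial status and tandem clustering; read-count matrices with
known presence truth; and membrane proteins with known TM topology. Default
counts follow the H. armigera repertoire (197 genes: 3 CO2, 8 sugar,
2 GR43a-like and a 184-gene bitter clade holding 31/13/129 Types 1/2/3,
4 pseudogenes and 7 untypable partial models, with one 38-gene Type 3 tandem
array and one 9-gene Type 2 array).

Each gene is a point-mutated copy of a subfamily- (and, for bitter genes,
type-) specific ancestor protein, back-translated with uniform synonymous
codons. Ancestor proteins are random sequences fixed by the seed, not real
receptor sequences, so the repository ships no third-party data; anchors are
low-divergence copies of the ancestors. All output is a pure function of
(spec, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Data.CodonTable import standard_dna_table

from .expression_profile import ExpressionMatrix
from .genome_io import (
    GeneModel, ProteinRecord, Scaffold, gene_models_to_gff3, write_fasta,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_CODONS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()
_STOP_CODONS = sorted(standard_dna_table.stop_codons)

# ancestor protein lengths (aa, incl. start Met); bitter type lengths are
# resampled per gene into the type's band with a >=10 aa guard margin
ANCESTOR_LENGTHS = {
    "co2": 450, "sugar": 440, "gr43a_like": 430,
    "type1": 400, "type2": 435, "type3": 300,
}
TYPE_LENGTH_BANDS = {"type1": (380, 420), "type2": (411, 470), "type3": (210, 350)}
ANCHORS_PER_SUBFAMILY = {"co2": 3, "sugar": 4, "gr43a_like": 3, "bitter": 3}


@dataclass(frozen=True)
class ArraySpec:
    """A tandem array to implant on a dedicated scaffold."""

    bitter_type: str
    size: int
    gap_range: tuple[int, int] = (3500, 4200)


@dataclass(frozen=True)
class RepertoireSpec:
    n_co2: int = 3
    n_sugar: int = 8
    n_gr43a_like: int = 2
    n_type1: int = 31
    n_type2: int = 13
    n_type3: int = 129
    # additional bitter genes carrying defects (short-intronless band): an
    # internal stop (pseudogene) or a missing terminus (partial); they land
    # in the summary's pseudo / unknown columns
    n_pseudogenes: int = 4
    n_partial: int = 7
    divergence: float = 0.10          # substitutions/site, gene vs type ancestor
    anchor_divergence: float = 0.02
    arrays: tuple[ArraySpec, ...] = (
        ArraySpec("type3", 38, (3500, 4200)),   # scaffold-139-like, span < 0.2 Mb
        ArraySpec("type2", 9, (3800, 4500)),    # scaffold-152-like, span < 0.05 Mb
    )
    intergenic_range: tuple[int, int] = (2000, 8000)
    genes_per_scaffold: int = 8
    flank: int = 1000

    def validate(self) -> None:
        if min(self.n_co2, self.n_sugar, self.n_gr43a_like, self.n_type1,
               self.n_type2, self.n_type3, self.n_pseudogenes, self.n_partial) < 0:
            raise ValueError("gene counts must be >= 0")
        for arr in self.arrays:
            if arr.bitter_type not in TYPE_LENGTH_BANDS:
                raise ValueError(f"array of unknown bitter type {arr.bitter_type!r}")
            have = {"type1": self.n_type1, "type2": self.n_type2,
                    "type3": self.n_type3}[arr.bitter_type]
            if arr.size > have:
                raise ValueError(
                    f"array of {arr.size} {arr.bitter_type} genes exceeds the "
                    f"{have} genes of that type"
                )
        for lo, hi in TYPE_LENGTH_BANDS.values():
            if lo >= hi:
                raise ValueError("empty type length band")


@dataclass
class RepertoireResult:
    scaffolds: dict[str, Scaffold]
    gene_models: list[GeneModel]
    manifest: pd.DataFrame
    anchors: list[ProteinRecord]
    anchor_map: dict[str, str]
    spec: RepertoireSpec
    seed: int

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "gff3": outdir / "genes.gff3",
            "anchors": outdir / "anchors.fasta",
            "anchor_map": outdir / "anchors.tsv",
            "manifest": outdir / "truth_manifest.tsv",
            "params": outdir / "generator_params.yaml",
        }
        write_fasta(self.scaffolds.values(), paths["genome"])
        gene_models_to_gff3(self.gene_models, paths["gff3"])
        write_fasta(self.anchors, paths["anchors"])
        with open(paths["anchor_map"], "w") as fh:
            fh.write("anchor_id\tsubfamily\n")
            for aid, sf in self.anchor_map.items():
                fh.write(f"{aid}\t{sf}\n")
        self.manifest.to_csv(paths["manifest"], sep="\t", index=False)
        params = {"seed": self.seed, **_spec_to_dict(self.spec)}
        paths["params"].write_text(yaml.safe_dump(params, sort_keys=True))
        return paths


def _spec_to_dict(spec: RepertoireSpec) -> dict:
    d = {k: v for k, v in vars(spec).items() if k != "arrays"}
    d["arrays"] = [
        {"bitter_type": a.bitter_type, "size": a.size, "gap_range": list(a.gap_range)}
        for a in spec.arrays
    ]
    for k in ("intergenic_range",):
        d[k] = list(d[k])
    return d


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(list(AMINO_ACIDS), size=length - 1))
    return "M" + body


def _mutate(rng: np.random.Generator, protein: str, rate: float) -> str:
    out = list(protein)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        if i == 0:
            continue  # keep the start Met
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _fit_length(rng: np.random.Generator, protein: str, target: int) -> str:
    if target <= len(protein):
        return protein[:target]
    extra = "".join(rng.choice(list(AMINO_ACIDS), size=target - len(protein)))
    return protein + extra


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [
        _CODONS[aa][int(rng.integers(len(_CODONS[aa])))] for aa in protein
    ]
    return "".join(codons)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@dataclass
class _GeneDraft:
    gene_id: str
    subfamily: str
    bitter_type: str          # classification truth; "" for non-bitter
    protein: str              # structural protein (no flags applied yet)
    structural_band: str = "" # length/exon band the gene is built in
    pseudogene: bool = False
    partial: str = "none"
    array_id: str = ""

    genomic_seq: str = ""
    exons_local: list[tuple[int, int]] = field(default_factory=list)
    strand: str = "+"


def _build_gene_sequence(rng: np.random.Generator, draft: _GeneDraft) -> None:
    """Back-translate, apply pseudogene/partial edits, insert introns, and fix
    the local genomic layout of one gene (plus-sense; strand applied later)."""
    cds = _back_translate(rng, draft.protein)
    if draft.partial in ("missing_n", "missing_both"):
        cds = "AAG" + cds[3:]  # start codon lost (M -> K)
    if draft.pseudogene:
        mid = (len(cds) // 6) * 3  # in-frame stop well inside the ORF
        cds = cds[:mid] + "TAA" + cds[mid + 3:]
    if draft.partial not in ("missing_c", "missing_both"):
        cds += _STOP_CODONS[int(rng.integers(len(_STOP_CODONS)))]

    if draft.structural_band == "type1":
        n_exons = int(rng.integers(3, 5))  # 3 or 4
        cuts = sorted(rng.choice(
            np.arange(60, len(cds) - 60), size=n_exons - 1, replace=False
        ).tolist())
        pieces, prev = [], 0
        for c in cuts:
            pieces.append(cds[prev:c])
            prev = c
        pieces.append(cds[prev:])
        seq_parts: list[str] = []
        exons: list[tuple[int, int]] = []
        pos = 0
        for i, piece in enumerate(pieces):
            exons.append((pos, pos + len(piece)))
            seq_parts.append(piece)
            pos += len(piece)
            if i < len(pieces) - 1:
                intron = "GT" + _random_dna(rng, int(rng.integers(56, 197))) + "AG"
                seq_parts.append(intron)
                pos += len(intron)
        draft.genomic_seq = "".join(seq_parts)
        draft.exons_local = exons
    else:
        draft.genomic_seq = cds
        draft.exons_local = [(0, len(cds))]


def _place_genes(rng: np.random.Generator, scaffold_id: str,
                 drafts: list[_GeneDraft], gap_range: tuple[int, int],
                 flank: int) -> tuple[Scaffold, list[GeneModel]]:
    from Bio.Seq import Seq

    parts: list[str] = [_random_dna(rng, flank)]
    pos = flank
    models: list[GeneModel] = []
    for i, d in enumerate(drafts):
        if i > 0:
            gap = int(rng.integers(gap_range[0], gap_range[1] + 1))
            parts.append(_random_dna(rng, gap))
            pos += gap
        d.strand = "+" if rng.random() < 0.5 else "-"
        gseq = d.genomic_seq
        glen = len(gseq)
        if d.strand == "+":
            exons = [(pos + s, pos + e) for s, e in d.exons_local]
            parts.append(gseq)
        else:
            exons = sorted((pos + glen - e, pos + glen - s) for s, e in d.exons_local)
            parts.append(str(Seq(gseq).reverse_complement()))
        cds = _spliced(gseq, d.exons_local)
        models.append(GeneModel(d.gene_id, scaffold_id, d.strand, exons, cds))
        pos += glen
    parts.append(_random_dna(rng, flank))
    return Scaffold(scaffold_id, "".join(parts)), models


def _spliced(gseq: str, exons_local: list[tuple[int, int]]) -> str:
    return "".join(gseq[s:e] for s, e in exons_local)


def generate_repertoire_genome(spec: RepertoireSpec = RepertoireSpec(),
                               seed: int = 0) -> RepertoireResult:
    """Generate scaffolds, gene models, anchors and the truth manifest.

    Defective genes (pseudogene / partial) are generated in addition to the
    typed counts and never join tandem arrays (arrays emulate clean
    duplicated blocks). Byte-identical output for identical (spec, seed).
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    ancestors = {
        name: _random_protein(rng, length) for name, length in ANCESTOR_LENGTHS.items()
    }

    # anchors: low-divergence copies of the ancestors
    anchors: list[ProteinRecord] = []
    anchor_map: dict[str, str] = {}
    for sf, count in ANCHORS_PER_SUBFAMILY.items():
        sources = (["type1", "type2", "type3"] if sf == "bitter" else [sf]) * count
        for i in range(count):
            aid = f"ANC_{sf}_{i + 1}"
            anchors.append(ProteinRecord(
                aid, _mutate(rng, ancestors[sources[i]], spec.anchor_divergence)
            ))
            anchor_map[aid] = sf

    # gene drafts; pseudogene/partial genes are extra short-intronless
    # bitter genes whose classification truth is "unknown"
    drafts: list[_GeneDraft] = []
    partial_kinds = ["missing_n", "missing_c", "missing_both"]
    plan = [
        ("co2", "", spec.n_co2, "clean"), ("sugar", "", spec.n_sugar, "clean"),
        ("gr43a_like", "", spec.n_gr43a_like, "clean"),
        ("bitter", "type1", spec.n_type1, "clean"),
        ("bitter", "type2", spec.n_type2, "clean"),
        ("bitter", "type3", spec.n_type3, "clean"),
        ("bitter", "type3", spec.n_pseudogenes, "pseudo"),
        ("bitter", "type3", spec.n_partial, "partial"),
    ]
    gid = 0
    for sf, band, count, kind in plan:
        for j in range(count):
            gid += 1
            anc = ancestors[band or sf]
            protein = _mutate(rng, anc, spec.divergence)
            if band:
                lo, hi = TYPE_LENGTH_BANDS[band]
                protein = _fit_length(rng, protein, int(rng.integers(lo, hi + 1)))
            truth_type = band if kind == "clean" else "unknown"
            draft = _GeneDraft(f"SynGR{gid}", sf, truth_type, protein,
                               structural_band=band)
            if kind == "pseudo":
                draft.pseudogene = True
            elif kind == "partial":
                draft.partial = partial_kinds[j % 3]
            drafts.append(draft)

    # assign arrays (consume clean genes of the required type, in order)
    by_type: dict[str, list[_GeneDraft]] = {}
    for d in drafts:
        if d.bitter_type in TYPE_LENGTH_BANDS:
            by_type.setdefault(d.bitter_type, []).append(d)
    array_members: dict[str, list[_GeneDraft]] = {}
    cursor = {t: 0 for t in by_type}
    for ai, arr in enumerate(spec.arrays, start=1):
        pool = by_type[arr.bitter_type]
        take = pool[cursor[arr.bitter_type]: cursor[arr.bitter_type] + arr.size]
        cursor[arr.bitter_type] += arr.size
        aid = f"array_{ai}"
        for d in take:
            d.array_id = aid
        array_members[aid] = take

    for d in drafts:
        _build_gene_sequence(rng, d)

    # scaffold layout: one scaffold per array, then packed scaffolds
    scaffolds: dict[str, Scaffold] = {}
    models: list[GeneModel] = []
    scaffold_no = 0
    for ai, arr in enumerate(spec.arrays, start=1):
        scaffold_no += 1
        sid = f"scaffold_{scaffold_no}"
        scaf, ms = _place_genes(rng, sid, array_members[f"array_{ai}"],
                                arr.gap_range, spec.flank)
        scaffolds[sid] = scaf
        models.extend(ms)
    rest = [d for d in drafts if not d.array_id]
    for i in range(0, len(rest), spec.genes_per_scaffold):
        scaffold_no += 1
        sid = f"scaffold_{scaffold_no}"
        scaf, ms = _place_genes(rng, sid, rest[i : i + spec.genes_per_scaffold],
                                spec.intergenic_range, spec.flank)
        scaffolds[sid] = scaf
        models.extend(ms)

    model_by_id = {m.gene_id: m for m in models}
    rows = []
    for d in drafts:
        m = model_by_id[d.gene_id]
        rows.append({
            "gene_id": d.gene_id, "scaffold": m.scaffold_id,
            "start": m.start, "end": m.end, "strand": m.strand,
            "subfamily": d.subfamily, "bitter_type": d.bitter_type or "not_bitter",
            "exon_count": m.exon_count, "length_aa": len(d.protein),
            "pseudogene": d.pseudogene, "partial": d.partial,
            "array_id": d.array_id or "none",
        })
    manifest = pd.DataFrame(rows).sort_values("gene_id", kind="stable").reset_index(drop=True)
    return RepertoireResult(scaffolds, models, manifest, anchors, anchor_map, spec, seed)


# ---------------------------------------------------------------------------
# Expression simulation

def simulate_expression_means(gene_ids: list[str], library_ids: list[str],
                              seed: int, expressed_fraction: float = 84 / 197,
                              expressed_level: float = 100.0,
                              max_breadth: int = 4) -> pd.DataFrame:
    """True mean relative abundances: each expressed gene is active in 1 to
    ``max_breadth`` random libraries at ``expressed_level`` RPKM, silent
    elsewhere."""
    rng = np.random.default_rng(seed)
    means = pd.DataFrame(0.0, index=list(gene_ids), columns=list(library_ids))
    n_expr = round(expressed_fraction * len(gene_ids))
    chosen = rng.choice(len(gene_ids), size=n_expr, replace=False)
    for gi in sorted(chosen.tolist()):
        breadth = int(rng.integers(1, min(max_breadth, len(library_ids)) + 1))
        libs = rng.choice(len(library_ids), size=breadth, replace=False)
        means.iloc[gi, sorted(libs.tolist())] = expressed_level
    return means


def simulate_expression_counts(means: pd.DataFrame, gene_lengths: pd.Series,
                               library_sizes: pd.Series, seed: int,
                               cutoff: float = 1.0,
                               ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw Poisson counts with mean = abundance x gene length (kb) x library
    size (millions); returns the count matrix and the boolean truth matrix of
    (gene, library) pairs whose generating mean abundance is >= cutoff."""
    if (means < 0).any().any():
        raise ValueError("mean abundances must be >= 0")
    rng = np.random.default_rng(seed)
    kb = gene_lengths.loc[means.index] / 1_000.0
    millions = library_sizes.loc[means.columns] / 1_000_000.0
    lam = means.mul(kb, axis=0).mul(millions, axis=1)
    counts = pd.DataFrame(
        rng.poisson(lam.to_numpy()), index=means.index, columns=means.columns
    )
    truth = means >= cutoff
    em = ExpressionMatrix(counts, gene_lengths.loc[means.index],
                          library_sizes.loc[means.columns])
    return em, truth


# ---------------------------------------------------------------------------
# Membrane proteins

_HYDROPHOBIC = "IVLF"
_INSIDE_LOOP = "KRKRDE"    # K/R-rich cytoplasmic loops
_OUTSIDE_LOOP = "DEDENQST" # K/R-free extracellular loops

TM_SEGMENT_LENGTH = 21
MIN_LOOP = 5


def generate_membrane_protein(k: int, length: int, seed: int,
                              n_inside: bool | None = None,
                              ) -> tuple[ProteinRecord, dict]:
    """A synthetic membrane protein with exactly ``k`` hydrophobic 21-mers.

    Loops alternate sides; cytoplasmic loops are K/R-rich and extracellular
    loops K/R-free, so the positive-inside rule recovers the generated
    orientation. Truth dict reports tmd_count, n_terminus, c_terminus and the
    implanted segments.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    need = k * TM_SEGMENT_LENGTH + (k + 1) * MIN_LOOP
    if length < need:
        raise ValueError(f"length {length} cannot hold {k} segments (needs >= {need})")
    rng = np.random.default_rng(seed)
    if n_inside is None:
        n_inside = bool(rng.random() < 0.5)

    loop_total = length - k * TM_SEGMENT_LENGTH
    n_loops = k + 1
    base = loop_total // n_loops
    loop_lengths = [base + (1 if i < loop_total % n_loops else 0) for i in range(n_loops)]

    def loop_seq(i: int, n: int) -> str:
        inside = n_inside if i % 2 == 0 else not n_inside
        alpha = _INSIDE_LOOP if inside else _OUTSIDE_LOOP
        return "".join(rng.choice(list(alpha), size=n))

    parts: list[str] = []
    segments: list[tuple[int, int]] = []
    pos = 0
    for i in range(k):
        lp = loop_seq(i, loop_lengths[i])
        parts.append(lp)
        pos += len(lp)
        tm = "".join(rng.choice(list(_HYDROPHOBIC), size=TM_SEGMENT_LENGTH))
        segments.append((pos, pos + TM_SEGMENT_LENGTH))
        parts.append(tm)
        pos += TM_SEGMENT_LENGTH
    parts.append(loop_seq(k, loop_lengths[k]))
    sequence = "".join(parts)

    if k == 0:
        truth = {"tmd_count": 0, "n_terminus": "n/a", "c_terminus": "n/a",
                 "segments": []}
    else:
        n_term = "inside" if n_inside else "outside"
        same = k % 2 == 0
        c_term = n_term if same else ("outside" if n_inside else "inside")
        truth = {"tmd_count": k, "n_terminus": n_term, "c_terminus": c_term,
                 "segments": segments}
    return ProteinRecord(f"synTM_k{k}_s{seed}", sequence), truth
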