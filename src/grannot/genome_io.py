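"""Sequence and gene-model I/O.

All genomic intervals inside the package are 0-based half-open; GFF3
coordinates (1-based inclusive) are converted at the parsing/writing
boundary so interval arithmetic never carries ±1 bookkeeping.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import gffutils
import pandas as pd
from Bio.Seq import Seq

log = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZXU*")


@dataclass(frozen=True)
class Scaffold:
    """A genome scaffold: an id and an uppercase DNA string over {A,C,G,T,N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence; '*' marks translated in-frame stops."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty protein sequence for {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


class Translation(NamedTuple):
    protein: str
    internal_stop: bool
    has_terminal_stop: bool


@dataclass
class GeneModel:
    """A gene locus on a scaffold.

    ``exons`` are non-overlapping (start, end) intervals sorted by genomic
    position regardless of strand; ``cds`` is spliced in transcription order
    (reverse-complemented for minus-strand genes); ``protein`` is the
    translation with the terminal stop trimmed but internal stops retained.
    """

    gene_id: str
    scaffold_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: str
    protein: str = ""
    internal_stop: bool = False
    has_terminal_stop: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons {(s1, e1)} and {(s2, e2)}")
        if sum(e - s for s, e in self.exons) != len(self.cds):
            raise ValueError(f"{self.gene_id}: CDS length does not equal summed exon lengths")
        if not self.protein and self.cds:
            tr = translate_cds(self.cds)
            self.protein = tr.protein
            self.internal_stop = tr.internal_stop
            self.has_terminal_stop = tr.has_terminal_stop

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def intronless(self) -> bool:
        return self.exon_count == 1

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length_aa(self) -> int:
        return len(self.protein)


@dataclass(frozen=True)
class FastaRecord:
    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Parse FASTA; order preserved, sequences uppercased, folded lines joined.

    Raises on duplicate ids (naming the id) and on malformed headers (naming
    the line number).
    """
    records: list[FastaRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        records.append(FastaRecord(header, "".join(chunks).upper()))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise ValueError(f"{path}: malformed FASTA header at line {lineno}")
                if name in seen:
                    raise ValueError(f"{path}: duplicate FASTA record id {name!r}")
                seen.add(name)
                header, chunks = name, []
            else:
                if header is None:
                    raise ValueError(
                        f"{path}: sequence data before any FASTA header at line {lineno}"
                    )
                chunks.append(line.strip())
    flush()
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_scaffolds(path: str | Path) -> dict[str, Scaffold]:
    return {r.id: Scaffold(r.id, r.sequence) for r in read_fasta(path)}


def read_proteins(path: str | Path) -> list[ProteinRecord]:
    return [ProteinRecord(r.id, r.sequence) for r in read_fasta(path)]


def translate_cds(cds: str) -> Translation:
    """Translate a CDS with the standard genetic code.

    The terminal stop codon, if present, is trimmed from the returned protein;
    internal stops are retained as '*' and flagged. Codons containing N
    translate to 'X' and never call a stop. Trailing bases beyond the last
    full codon are ignored with a warning.
    """
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    if len(cds) % 3:
        warnings.warn(
            f"CDS length {len(cds)} is not a multiple of 3; ignoring trailing bases",
            stacklevel=2,
        )
        cds = cds[: len(cds) - len(cds) % 3]
    aa = str(Seq(cds).translate())
    has_terminal_stop = aa.endswith("*")
    protein = aa[:-1] if has_terminal_stop else aa
    return Translation(protein, "*" in protein, has_terminal_stop)


def _spliced_cds(scaffold: Scaffold, parts: list[tuple[int, int]], strand: str) -> str:
    seq = "".join(scaffold.sequence[s:e] for s, e in sorted(parts))
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def read_gff3(path: str | Path, scaffolds: dict[str, Scaffold]) -> list[GeneModel]:
    """Build gene models from a GFF3 file.

    Expects gene → mRNA → exon (and optionally CDS) features; exons parented
    directly on a gene are also accepted. CDS features, when present, define
    the coding sequence and their phase is honoured; otherwise exons are used
    with phase 0 assumed (logged).
    """
    with open(path) as fh:
        has_features = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_features:
        return []
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    seen: set[str] = set()
    for gene in db.features_of_type("gene"):
        gene_id = gene.id
        if gene_id in seen:
            raise ValueError(f"duplicate gene id {gene_id!r} in {path}")
        seen.add(gene_id)
        if gene.seqid not in scaffolds:
            raise ValueError(f"{gene_id}: unknown scaffold {gene.seqid!r}")
        scaffold = scaffolds[gene.seqid]

        mrnas = list(db.children(gene, featuretype="mRNA"))
        container = mrnas[0] if mrnas else gene
        exon_feats = list(db.children(container, featuretype="exon", order_by="start"))
        cds_feats = list(db.children(container, featuretype="CDS", order_by="start"))
        if not exon_feats and cds_feats:
            exon_feats = cds_feats
        if not exon_feats:
            raise ValueError(f"{gene_id}: no exon or CDS features")

        exons = [(f.start - 1, f.end) for f in exon_feats]  # GFF3 -> 0-based half-open
        for s, e in exons:
            if s < 0 or e > scaffold.length or s >= e:
                raise ValueError(
                    f"{gene_id}: exon ({s + 1}, {e}) outside scaffold "
                    f"{scaffold.id!r} bounds (length {scaffold.length})"
                )
        exons.sort()
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"{gene_id}: overlapping exons in one mRNA")

        strand = gene.strand
        if cds_feats:
            parts = sorted((f.start - 1, f.end) for f in cds_feats)
            # first CDS segment in transcription order carries the phase
            first = cds_feats[-1] if strand == "-" else cds_feats[0]
            phase = int(first.frame) if first.frame not in (".", None) else _warn_phase(gene_id)
            cds = _spliced_cds(scaffold, parts, strand)[phase:]
        else:
            log.warning("%s: no CDS features; translating exons with phase 0", gene_id)
            cds = _spliced_cds(scaffold, exons, strand)
        models.append(GeneModel(gene_id, scaffold.id, strand, exons, cds))
    return models


def _warn_phase(gene_id: str) -> int:
    log.warning("%s: CDS phase missing; assuming phase 0", gene_id)
    return 0


def gene_models_to_gff3(models: list[GeneModel], path: str | Path) -> None:
    """Write gene models back out as gene/mRNA/exon/CDS GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            g0, g1 = gm.start + 1, gm.end
            base = f"{gm.scaffold_id}\tgrannot"
            fh.write(f"{base}\tgene\t{g0}\t{g1}\t.\t{gm.strand}\t.\tID={gm.gene_id}\n")
            mid = f"{gm.gene_id}.t1"
            fh.write(f"{base}\tmRNA\t{g0}\t{g1}\t.\t{gm.strand}\t.\tID={mid};Parent={gm.gene_id}\n")
            tx_order = gm.exons if gm.strand == "+" else list(reversed(gm.exons))
            phases = {}
            acc = 0
            for s, e in tx_order:
                phases[(s, e)] = (3 - acc % 3) % 3
                acc += e - s
            for i, (s, e) in enumerate(gm.exons, 1):
                fh.write(
                    f"{base}\texon\t{s + 1}\t{e}\t.\t{gm.strand}\t.\t"
                    f"ID={mid}.exon{i};Parent={mid}\n"
                )
            for i, (s, e) in enumerate(gm.exons, 1):
                fh.write(
                    f"{base}\tCDS\t{s + 1}\t{e}\t.\t{gm.strand}\t{phases[(s, e)]}\t"
                    f"ID={mid}.cds{i};Parent={mid}\n"
                )


# ---------------------------------------------------------------------------
# Tabular report I/O

PER_GENE_SCHEMA: dict[str, str] = {
    "gene_id": "string",
    "scaffold": "string",
    "start": "int64",
    "end": "int64",
    "strand": "string",
    "subfamily": "string",
    "bitter_type": "string",
    "length_aa": "int64",
    "exon_count": "int64",
    "pseudogene": "bool",
    "partial": "string",
}

SUMMARY_SCHEMA: dict[str, str] = {
    "assembly": "string",
    "total": "int64",
    "co2": "int64",
    "sugar": "int64",
    "gr43a_like": "int64",
    "pseudo": "int64",
    "bitter_clade": "int64",
    "bitter_total": "int64",
    "type1": "int64",
    "type2": "int64",
    "type3": "int64",
    "unknown": "int64",
    "partial_flagged": "int64",
}


def write_table(df: pd.DataFrame, path: str | Path, schema: dict[str, str]) -> None:
    cols = list(schema)
    out = df.reindex(columns=cols).astype(schema)
    out.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, schema: dict[str, str]) -> pd.DataFrame:
    bools = [c for c, t in schema.items() if t == "bool"]
    df = pd.read_csv(
        path, sep="\t",
        dtype={c: t for c, t in schema.items() if t != "bool"},
        converters={c: lambda v: v == "True" for c in bools},
    )
    return df.astype(schema)[list(schema)]


def write_tables(summary, outdir: str | Path) -> dict[str, Path]:
    """Write a repertoire summary (per-gene table + Table-1-style row) as TSVs.

    Re-reading with :func:`read_tables` reproduces both frames bit-exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "per_gene": outdir / "per_gene_classification.tsv",
        "summary": outdir / "repertoire_summary.tsv",
    }
    write_table(summary.per_gene, paths["per_gene"], PER_GENE_SCHEMA)
    write_table(summary.table, paths["summary"], SUMMARY_SCHEMA)
    return paths


def read_tables(outdir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    outdir = Path(outdir)
    return (
        read_table(outdir / "per_gene_classification.tsv", PER_GENE_SCHEMA),
        read_table(outdir / "repertoire_summary.tsv", SUMMARY_SCHEMA),
    )
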