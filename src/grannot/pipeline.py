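"""End-to-end orchestration: annotate -> classify -> type -> cluster ->
express -> topology, with a YAML config, seeded reproducibility and a run
manifest (parameters + output checksums). Rerunning an identical config
reproduces byte-identical outputs; each stage also works standalone on the
previous stage's files.
"""
from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bitter_typing, cluster_analysis, expression_profile, genome_io
from . import homology_search as hs
from . import phylo_classify as pc
from . import topology as topo

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome: str = ""
    gff3: str = ""
    anchors_fasta: str = ""
    anchors_map: str = ""
    outdir: str = "grannot_run"
    seed: int = 0

    # homology search (optional stage; runs if query_fasta is set)
    query_fasta: str = ""
    word_size: int = 3
    seed_threshold: float = 11.0
    x_drop: float = 20.0
    min_score: float = 50.0
    locus_max_gap: int = 10_000

    # classification
    distance_model: str = "poisson"
    bootstrap_replicates: int = 0

    # bitter typing
    type2_min_length: int = bitter_typing.TYPE2_MIN_LENGTH
    type3_max_length: int = bitter_typing.TYPE3_MAX_LENGTH
    type3_min_length: int = bitter_typing.TYPE3_MIN_LENGTH

    # tandem arrays
    array_max_gap: int = cluster_analysis.DEFAULT_MAX_GAP
    min_array_size: int = cluster_analysis.DEFAULT_MIN_ARRAY_SIZE

    # expression (optional stage; runs if counts_tsv is set)
    counts_tsv: str = ""
    gene_lengths_tsv: str = ""
    library_sizes_tsv: str = ""
    library_groups_yaml: str = ""
    expression_cutoff: float = expression_profile.DEFAULT_CUTOFF_RPKM

    # topology
    topology_windows: list[int] = field(default_factory=lambda: list(topo.CONSENSUS_WINDOWS))
    topology_threshold: float = topo.DEFAULT_THRESHOLD
    min_tm_len: int = topo.DEFAULT_MIN_TM_LEN
    merge_gap: int = topo.DEFAULT_MERGE_GAP

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def template_yaml() -> str:
    """A full-defaults config template."""
    return yaml.safe_dump(PipelineConfig().to_dict(), sort_keys=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def read_anchor_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["anchor_id"], df["subfamily"]))


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every configured stage; returns the run directory.

    A stage failure aborts with the stage name; outputs already written are
    retained next to a FAILED marker naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for p, what in ((config.genome, "genome FASTA"), (config.gff3, "gene-model GFF3"),
                    (config.anchors_fasta, "anchor FASTA"), (config.anchors_map, "anchor map")):
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"{what} not found: {p!r}")

    stage = "load"
    try:
        scaffolds = genome_io.read_scaffolds(config.genome)
        genes = genome_io.read_gff3(config.gff3, scaffolds)
        anchors = genome_io.read_proteins(config.anchors_fasta)
        anchor_map = read_anchor_map(config.anchors_map)
        log.info("loaded %d scaffolds, %d gene models, %d anchors",
                 len(scaffolds), len(genes), len(anchors))

        outputs: list[Path] = []

        if config.query_fasta:
            stage = "annotate"
            outputs += _stage_homology(config, scaffolds, outdir)

        stage = "classify"
        assignments = _stage_classify(config, genes, anchors, anchor_map, outdir, outputs)

        stage = "type"
        summary, classifications = _stage_type(config, genes, assignments, outdir, outputs)

        stage = "cluster"
        outputs.append(_stage_cluster(config, classifications, outdir))

        if config.counts_tsv:
            stage = "express"
            outputs += _stage_express(config, outdir)

        stage = "topology"
        outputs.append(_stage_topology(config, genes, outdir))

        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "n_scaffolds": len(scaffolds),
            "n_genes": len(genes),
            "checksums": {p.name: _sha256(p) for p in sorted(set(outputs))},
        }
        (outdir / "run_manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir


def _stage_homology(config: PipelineConfig, scaffolds, outdir: Path) -> list[Path]:
    queries = genome_io.read_proteins(config.query_fasta)
    params = hs.SearchParams(config.word_size, config.seed_threshold,
                             config.x_drop, config.min_score)
    all_hsps: list[hs.HSP] = []
    for scaf in scaffolds.values():
        frames = hs.six_frame_translate(scaf)
        for q in queries:
            all_hsps.extend(hs.search_translated(q, frames, params))
    loci = hs.merge_hsps_to_loci(all_hsps, config.locus_max_gap)
    hsp_path = outdir / "hsps.tsv"
    pd.DataFrame([
        {"query": h.query_id, "scaffold": h.scaffold_id, "strand": h.strand,
         "frame": h.frame,
         "genomic_start": h.genomic_span[0] + 1, "genomic_end": h.genomic_span[1],
         "score": h.score, "identities": h.identities}
        for h in all_hsps
    ], columns=["query", "scaffold", "strand", "frame", "genomic_start",
                "genomic_end", "score", "identities"],
    ).to_csv(hsp_path, sep="\t", index=False)
    loci_path = outdir / "candidate_loci.tsv"
    pd.DataFrame([
        {"scaffold": l.scaffold_id, "strand": l.strand,
         "start": l.genomic_span[0] + 1, "end": l.genomic_span[1],
         "n_hsps": len(l.supporting_hsps), "best_query": l.best_query}
        for l in loci
    ], columns=["scaffold", "strand", "start", "end", "n_hsps", "best_query"],
    ).to_csv(loci_path, sep="\t", index=False)
    log.info("annotate: %d HSPs, %d candidate loci", len(all_hsps), len(loci))
    return [hsp_path, loci_path]


def _tree_protein(gm: genome_io.GeneModel) -> genome_io.ProteinRecord | None:
    seq = pc.longest_orf_segment(gm.protein) if gm.internal_stop else gm.protein
    return genome_io.ProteinRecord(gm.gene_id, seq) if seq else None


def _stage_classify(config, genes, anchors, anchor_map, outdir, outputs,
                    ) -> dict[str, str]:
    if not genes:
        (outdir / "subfamily_assignments.tsv").write_text(
            "gene_id\tsubfamily\tambiguous\tanchor_support\n")
        outputs.append(outdir / "subfamily_assignments.tsv")
        return {}
    proteins = [p for p in (_tree_protein(g) for g in genes) if p is not None]
    tree, assignments, _ = pc.classify_repertoire(
        proteins, anchors, anchor_map,
        bootstrap_replicates=config.bootstrap_replicates,
        seed=config.seed, model=config.distance_model,
    )
    tree_path = outdir / "gr_tree.nwk"
    tree.write(str(tree_path))
    tsv = outdir / "subfamily_assignments.tsv"
    pd.DataFrame([
        {"gene_id": a.gene_id, "subfamily": a.subfamily, "ambiguous": a.ambiguous,
         "anchor_support": ",".join(a.anchor_support)}
        for a in assignments
    ]).to_csv(tsv, sep="\t", index=False)
    outputs += [tree_path, tsv]
    log.info("classify: %d genes assigned", len(assignments))
    return {a.gene_id: a.subfamily for a in assignments}


def _stage_type(config, genes, assignments, outdir, outputs):
    thresholds = dict(
        type2_min_length=config.type2_min_length,
        type3_max_length=config.type3_max_length,
        type3_min_length=config.type3_min_length,
    )
    classifications = [
        bitter_typing.classify_gene(g, assignments[g.gene_id], **thresholds)
        for g in genes
    ]
    summary = bitter_typing.summarize_repertoire(classifications)
    paths = genome_io.write_tables(summary, outdir)
    outputs += list(paths.values())
    log.info("type: %s", summary.counts)
    return summary, classifications


def _stage_cluster(config, classifications, outdir: Path) -> Path:
    rows = []
    for btype in ("type1", "type2", "type3"):
        arrays = cluster_analysis.detect_tandem_arrays(
            [c for c in classifications if c.subfamily == "bitter"],
            max_gap=config.array_max_gap, min_array_size=config.min_array_size,
            type_filter=btype,
        )
        for a in arrays:
            rows.append({
                "scaffold": a.scaffold_id, "bitter_type": a.bitter_type,
                "size": a.size, "span": a.span, "start": a.start + 1, "end": a.end,
                "members": ",".join(a.member_gene_ids),
            })
    path = outdir / "tandem_arrays.tsv"
    pd.DataFrame(rows, columns=["scaffold", "bitter_type", "size", "span",
                                "start", "end", "members"]).to_csv(
        path, sep="\t", index=False)
    log.info("cluster: %d arrays", len(rows))
    return path


def _stage_express(config, outdir: Path) -> list[Path]:
    em = expression_profile.read_counts_tsv(
        config.counts_tsv, config.gene_lengths_tsv, config.library_sizes_tsv)
    abundance = expression_profile.relative_abundance(em)
    presence = expression_profile.call_presence(abundance, config.expression_cutoff)
    apath = outdir / "abundance_rpkm.tsv"
    ppath = outdir / "presence_calls.tsv"
    with open(apath, "w") as fh:
        fh.write(f"# cutoff_rpkm={config.expression_cutoff}\n")
        abundance.to_csv(fh, sep="\t")
    with open(ppath, "w") as fh:
        fh.write(f"# cutoff_rpkm={config.expression_cutoff}\n")
        presence.to_csv(fh, sep="\t")
    out = [apath, ppath]
    if config.library_groups_yaml:
        groups = yaml.safe_load(Path(config.library_groups_yaml).read_text())
        summ = expression_profile.presence_summary(presence, groups)
        gpath = outdir / "presence_by_group.tsv"
        summ.per_group_detected.rename_axis("group").to_frame().to_csv(gpath, sep="\t")
        bpath = outdir / "gene_breadth.tsv"
        summ.gene_breadth.rename_axis("gene_id").to_frame().to_csv(bpath, sep="\t")
        out += [gpath, bpath]
        log.info("express: %d genes detected overall", summ.detected_total)
    return out


def _stage_topology(config, genes, outdir: Path) -> Path:
    rows = []
    min_window = min(config.topology_windows)
    for g in genes:
        if g.internal_stop or len(g.protein) < min_window:
            continue
        pred = topo.predict_consensus(
            genome_io.ProteinRecord(g.gene_id, g.protein),
            windows=tuple(config.topology_windows),
            threshold=config.topology_threshold,
            min_tm_len=config.min_tm_len, merge_gap=config.merge_gap,
        )
        rows.append({
            "protein": pred.protein_id, "tmd_count": pred.tmd_count,
            "n_terminus": pred.n_terminus, "c_terminus": pred.c_terminus,
            "votes": ",".join(map(str, pred.votes)) or str(pred.tmd_count),
            "segments": ";".join(f"{s + 1}-{e}" for s, e in pred.tm_segments),
        })
    path = outdir / "topology.tsv"
    pd.DataFrame(rows, columns=["protein", "tmd_count", "n_terminus",
                                "c_terminus", "votes", "segments"]).to_csv(
        path, sep="\t", index=False)
    log.info("topology: %d proteins", len(rows))
    return path
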