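# Methods

This note documents the models and procedures behind each pipeline stage,
the defaults and why they were chosen, what the synthetic data generator
does and does not emulate, and the numerical conventions that make runs
reproducible.

## Coordinates and gene models

All intervals are 0-based half-open internally; GFF3 (1-based inclusive) is
converted at the I/O boundary only. A gene model carries its exons sorted by
genomic position, a CDS spliced in transcription order (reverse-complemented
on the minus strand), and the translation with the terminal stop trimmed but
internal stops kept as `*`. When CDS features are present their phase is
honoured (the first segment in transcription order sets the offset);
otherwise exons are translated at phase 0 with a logged warning. Codons
containing N translate to `X` and never call a stop, so assembly gaps cannot
produce pseudogene calls. A CDS whose length is not a multiple of three is
translated with the trailing bases dropped and a warning — partial 3′ models
are then caught by the missing-terminal-stop flag rather than an error.

## Homology discovery

The discovery screen reproduces the role of a translated protein-to-genome
search without gapped alignment statistics: scaffolds are translated in six
frames (stops retained), and each reference protein is scanned with
word-size-3 BLOSUM62 seeds (word score ≥ 11), extended ungapped in both
directions with X-drop 20, keeping segments with score ≥ 50. `X` scores 0
against everything; stops in the subject frame score −10⁴, which both blocks
extension across them and excludes them from seeds. HSPs on one scaffold and
strand merge into a candidate locus while genomic gaps are ≤ 10 kb —
intron-sized gaps by construction, since final gene structure comes from the
curated GFF3, not from the screen. All thresholds are exposed; no E-values
are computed (raw score thresholds are transparent and deterministic, and
the screen's output is only a candidate list for curation).

Correctness is checked against an exhaustive oracle: on small scaffolds,
every diagonal whose best ungapped segment (max-subarray) clears the score
threshold and contains a seed word must be reported with at least that
score, and every reported score must equal an independent re-summation of
matrix entries.

## Subfamily classification

Genes are classified by placement in a distance tree with anchor proteins
of known subfamily (CO₂, sugar, GR43a-like, bitter; supplied as FASTA plus
an `anchor_id → subfamily` table — anchor sets are inputs, not constants).

**Alignment.** The multiple alignment behind the tree is produced by MAFFT
(`--auto --thread 1`, hence deterministic); internal stops are masked to `X`
before aligning, and pseudogenes enter as their longest stop-free translated
segment. The two-sequence distance API aligns with Biopython's global
aligner (BLOSUM62, gap open −11, extend −1).

**Distances.** p = mismatches over compared columns, where columns with a
gap in either sequence are excluded pairwise ("pairwise deletion"); the
Poisson correction d = −ln(1 − p) is capped (default 10.0) as p approaches
saturation. A zero-comparable-column pair is a hard error naming both
sequences. The Poisson model replaces a full empirical-matrix ML distance:
classification here depends on clade membership, not branch-length fidelity,
and the simple correction admits exact oracles.

**Tree.** Canonical Saitou–Nei neighbor joining, implemented in-package so
its determinism is pinned: Q-criterion ties break by the lexicographically
smallest pair of cluster labels (a cluster's label is its smallest leaf
name), and a negative branch length is clamped to zero with the deficit
moved to its sister so the joined pair's summed length is preserved. On an
additive matrix the tree reproduces the input distances exactly as tip-path
lengths; tests verify this against brute-force topology enumeration with
least-squares branch fitting (n = 6: 105 topologies) and cross-check splits
against scikit-bio's independent NJ on noisy matrices.

**Bootstrap.** Alignment columns are resampled with replacement, the tree is
rebuilt per replicate, and each original bipartition's support is the
percent of replicate trees containing it; seeded and reproducible, with a
degeneracy flag for single-column alignments. Default replicates in the
pipeline is 0 (supports are descriptive; classification does not use them).

**Assignment.** Each gene takes the subfamily of the nearest anchor by
patristic distance — the first anchor reached walking out of the gene's
leaf. Exact distance ties across different subfamilies break to the
lexicographically smallest subfamily and are flagged ambiguous with all tied
anchors recorded; otherwise the reported support lists the winning
subfamily's anchors inside the smallest clade (in the unrooted sense)
containing the gene and the deciding anchor. Two simpler rules were
rejected after testing at repertoire scale: a rooted ancestor walk inherits
the arbitrary placement of NJ's trifurcating root (genes in the root's
cluster escalate to the whole-tree anchor plurality), and a majority vote in
the smallest anchored enclosing clade fails when a ~130-gene expansion forms
a poorly resolved fan that other subfamily clusters attach inside — the
smallest clade containing a gene and its correct anchor can then span a
foreign anchor block that outvotes it. The nearest-anchor rule is
root-invariant, geometry-aware, and recovers 100% of generated subfamilies
at study scale across seeds.

## Bitter typing

Within the bitter clade: intron-containing genes (exon count ≥ 2) are
Type 1 regardless of length; intronless genes are Type 2 above 400 aa and
Type 3 in [200, 360) aa. The sharp thresholds (>400, <360) are the stated
bounds of the long and short classes; the uncovered intronless bands
([360, 400] and <200 aa) map to *unknown* rather than to a forced nearest
type. Pseudogene: an internal in-frame stop. Partial: no start methionine
(missing N), no terminal stop codon (missing C), or both; proteins under
100 aa are treated as fragments (missing both). Pseudogenes keep their
structural measurements but are excluded from the typed counts into their
own summary column; partial genes are never length-typed even when intron
status is known (a truncated model's length is not evidence). The summary
row therefore reports: subfamily counts, the bitter-clade size, the typed
bitter total (clade minus pseudogenes, which Type 1/2/3/unknown partition
exactly — enforced by assertion), and the raw partial-flag count separately,
since flag counts and summary-column counts need not coincide.

## Tandem arrays

Per scaffold, genes sorted by start are chained while the gap from one
gene's end to the next gene's start is ≤ `max_gap` (default 100 kb; spans
are reported per array so any published span figure can be checked
independently of the gap choice); chains of ≥ `min_array_size` (default 3)
are emitted. With a type filter, gaps are measured between consecutive genes
*of that type*, ignoring interleaved other-type genes — mixed-type scaffolds
otherwise fragment every array. Arrays are maximal and disjoint per
(scaffold, filter) query; the span bound
span ≤ (size − 1)·max_gap + Σ member lengths is property-tested.

## Expression profiling

Relative abundance is RPKM: counts / (gene length in kb × library size in
millions). A gene is *detected* in a library when RPKM ≥ cutoff (default
1.0, echoed into every output header); with cutoff 0 any mapped read
counts. Detection per library group needs one member library above cutoff;
per-gene tissue breadth is the number of detecting libraries. No
between-library differential testing is offered: the intended inputs are
single unreplicated libraries per tissue, where level comparisons are not
meaningful and presence/absence at a conservative cutoff is the honest
summary.

## Topology

Hydropathy is the windowed Kyte–Doolittle mean (window 19, odd, in [7, 25];
edge positions use the truncated window that fits; unknown residues score
0). TM segments are maximal runs of track positions ≥ 1.6, merged across
dips shorter than 4 positions, kept at ≥ 9 positions. Nine, not a physical
helix length: the windowed mean crosses a 1.6 threshold only where more
than half the window lies inside the helix, so a 21-residue helix under a
19-residue window yields an above-threshold run of roughly 13 positions —
a run-length minimum near 15 would silently reject genuine single helices.
The N-terminus is set by the positive-inside rule on the terminus-adjacent
loops (more K+R ⇒ cytoplasmic); on a tie — e.g. both terminal loops
K/R-free in a both-extracellular protein — the aggregate K+R count over
alternating loop sides decides. The C-terminus is always forced by parity
(odd TMD count ⇒ opposite sides), asserted as an invariant on every output.
The consensus operation replaces comparing several external predictors with
a window grid (15/19/21): median TMD count (ties to the lower value),
segments from the first parameterization achieving it, termini by majority
with parity repair.

Receptor proteins produced by the genome generator are mutated random
sequences, not hydrophobically realistic membrane proteins, so the pipeline
run on synthetic genomes reports 0 TMDs for them; topology recovery is
exercised on the dedicated membrane-protein generator below.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions: 197 genes — 3 CO₂ +
8 sugar + 2 GR43a-like + a 184-gene bitter clade holding 31 Type 1,
13 Type 2 and 129 Type 3 genes, 4 pseudogenes and 7 partial models — with a
38-gene Type 3 tandem array (gaps ~3.5–4.2 kb, span < 0.2 Mb) and a 9-gene
Type 2 array (span < 0.05 Mb); 13 anchors (3/4/3/3 per subfamily); an
expression truth in which 84/197 genes are active in 1–4 of 31 libraries.
Defective genes are generated in addition to the typed counts so the
summary row is exactly reproducible, and they never join arrays (arrays
emulate clean duplicated blocks). Since a partial model always classifies
as unknown here, the default partial count is the 7 that the summary's
unknown column holds; both counts are free parameters.

Mechanics: each subfamily (and each bitter type) has a random ancestor
protein fixed by the seed; genes are point-mutated copies (default 0.10
substitutions/site), length-adjusted into their type band with a ≥ 10 aa
guard margin around every threshold so type truth is unambiguous;
back-translation uses uniform synonymous codons; Type 1 genes get 3–4 exons
with GT…AG introns of 58–199 bp; pseudogenes get one internal TAA mid-ORF;
partials lose the start codon and/or terminal stop. Genes are placed on
scaffolds (random strand; arrays on dedicated scaffolds) with random
intergenic DNA. Anchors are low-divergence (0.02) copies of the ancestors —
generated sequences, deliberately not real receptor sequences, so the
repository ships no third-party data; real anchors can be supplied as
input. Expression counts are Poisson with mean abundance × length(kb) ×
depth(millions); at the default 100× cutoff for active genes the per-cell
misclassification probability is e⁻¹⁰⁰, so exact recovery is expected.
Membrane proteins are k hydrophobic 21-mers (I/V/L/F) between charged
loops, cytoplasmic loops K/R-rich and extracellular loops K/R-free, so the
implanted orientation is recoverable.

What passing on this generator does **not** show: robustness to indels and
domain-level divergence (substitution-only mutation), codon bias, sequencing
noise or mapping ambiguity in counts (Poisson with known truth), marginal
hydrophobicity or re-entrant/short helices in topology, and any claim about
specific real receptor counts — the generator reproduces the *structure* of
a published repertoire, not its sequences.

## Problem sizes and determinism

Everything is a pure function of (config, seed): NumPy `default_rng`
throughout, MAFFT pinned to one thread, NJ and all tie-breaks lexicographic,
and pipeline reruns byte-identical (verified in tests; the run manifest
records parameters and SHA-256 checksums of every output). The test suite
and the acceptance script run at desk scale: repertoires of 41–197 genes,
scaffolds ≤ 5 kb for exhaustive search oracles, trees ≤ 8 taxa for exact
additive checks (with full 105-topology enumeration at n = 6), 500–1000
random membrane proteins, and 10-seed type-recovery batches of 50 genes —
sizes chosen so every oracle remains exhaustive or closed-form.

## Known limitations

Ungapped HSPs understate homology across frameshifts; the screen relies on
locus merging to bridge them. Poisson/NJ is not an ML phylogeny and branch
supports are descriptive. The expression stage presumes uniquely-mapped
counts and cannot separate "absent" from "below detection". Topology is a
single hydropathy predictor family, not an HMM; signal peptides are not
modelled and would be called as a TM segment. Partial gene models are never
typed, which undercounts types when truncation is heavy.
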