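# Methods

## Problem and scope

Most genes initiate transcription from several transcription start sites
(TSSs). Bulk 5'-end assays (CAGE) show which TSSs a tissue uses, but not
whether two TSSs of one gene are used by the *same* single cells — they
could be co-activated, independently activated, or mutually exclusive
(burst competition, as in random monoallelic expression). `alttss`
implements the single-cell analysis that distinguishes these regimes from
5'-tag UMI data (STRT-like): molecule counting at curated CAGE-style TSS
windows, degradation filtering, major/minor TSS selection, pair
correlation analysis, and ratio-based per-cell statistics. Because the
original data require external downloads, the package ships a synthetic
generator that produces 5'-tag reads with the statistical structure the
analysis assumes, with full ground truth, so every stage is testable
end to end.

## The generative model (synthetic_data)

**Telegraph steady state.** Each TSS is modelled as a two-state promoter:
ON/OFF switching at rates `burst_on_rate` (k_on) and `burst_off_rate`
(k_off), transcription at `transcription_rate` (k_tx) while ON, and decay
at `degradation_rate` (δ). All rates are expressed per mean mRNA lifetime
(δ = 1 by default). Steady-state counts are drawn from the Beta-Poisson
representation: occupancy B ~ Beta(k_on/δ, k_off/δ), count | B ~
Poisson((k_tx/δ)·B). With the defaults k_on = k_off = 1 the occupancy is
uniform on (0,1) — visibly bursty but time-averaged by degradation, which
is exactly the regime in which co-activation is detectable as positive
pair correlation.

**Coupling modes** (per gene, `mode_probs`):

- *shared* — one occupancy draw B per cell feeds both TSSs: co-activation.
- *independent* — each TSS draws its own B.
- *exclusive* — one activity budget B is split u : (1−u) between the two
  TSSs with u ~ Beta(m·w1, m·w2); the concentration `exclusive_mixing`
  (m, default 0.5) encodes switching speed relative to degradation. Small
  m ≈ slow switching: a cell is caught using mostly one TSS →
  anti-correlation. Large m washes out to the shared-like limit.
- *bimodal_ratio* — cells belong to one of two groups
  (`bimodal_weight`), each with its own major fraction
  (`bimodal_fractions`, default 0.9 / 0.5); the pair total is drawn as in
  shared mode and split binomially. This reproduces the fixed-ratio
  violation that the per-cell binomial statistic is designed to find.

Exclusive and bimodal regimes are defined for TSS pairs; genes drawn with
one or three TSSs under those modes fall back to independent/shared.

**TSS asymmetry.** Per-TSS activity weights come from a sorted
Dirichlet(1.5) draw, so every gene has a well-defined ground-truth major
TSS and the population of genes spans near-exclusive major usage to
balanced pairs — the source of the ~40–50% "major-only" genes the
major-preference histogram shows.

**Cell size and capture.** Counts are scaled by a mean-one lognormal
per-cell size factor (`cell_size_sigma` = 0.4, CV ≈ 0.42), then thinned
binomially at `capture_efficiency` = 0.2 — detected molecules are a ~20%
sample of the transcriptome. The default per-TSS transcription rate (40
per lifetime) yields ≈ 4 *captured* molecules per TSS per cell for a
2-TSS gene, the regime in which pair correlations above 0.5 are
recoverable.

**Tag emission.** Each captured molecule becomes a 5' tag at its TSS
window centre plus Gaussian jitter (`scatter_sd` = 10 bp inside 60-bp
windows, so ≈ 97% of molecules fall within 50 bp of the centre); a
uniform degradation background is added along the gene body
(`background_rate` molecules per gene-kb per cell, default 0.5); spike-in
molecules (ERCC-style lengths 250–2,000 bp) map exactly at their 5' start
with probability 0.75 and uniformly along the transcript otherwise. Every
molecule gets a UMI drawn uniformly from 4^6 sequences — collisions are
generated, not corrected — and ≥ 1 reads per molecule from the
`duplication` distribution (default all ≥ 2, so no true molecule is lost
to the singleton rule). A `collision_free_umis` switch assigns sequential
UMIs within each (cell, position) group for conservation audits.

**What the generator does not emulate.** The background is uniform,
whereas real degradation has a 3' bias and localized hotspots — so with
the default light background the 20% reference filter removes nothing
(its removal fraction rises with `background_rate`, and reaches ~85% of
TSSs at background 40/kb/cell; the real data sat in between). The
bimodal-ratio group label is independent of all other genes, so the
ratio-group differential-expression screen is a true null on synthetic
data. There is no splicing, no sequence, no 3'-UTR cryptic peaks, no
cross-gene regulatory structure beyond cell size. Passing tests therefore
demonstrate correctness of the statistics and recoverability of the
coupling regimes — not robustness to every artefact of real libraries.

## Quantification (tag_quantify)

A *molecule* is a group of reads sharing (cell, chrom, strand, 5'
position, UMI); groups with a single read are removed. Collapsing uses
exact UMI matching (no edit-distance merging), and the singleton rule
applies per group, not per UMI globally. Malformed UMIs are counted and
dropped, never fatal.

TSS curation discards gene-less intervals and resolves overlaps: the
longer interval is trimmed on its overlapping side until a 1-bp gap
remains; equal lengths trim the downstream (larger-start) interval; an
interval strictly containing a shorter one cannot be fixed by a one-sided
trim and is dropped (logged). Coordinates are 0-based half-open
throughout; BED is native, and interval centres are floor midpoints.

Assignment is strand-aware containment of the molecule's 5' base in a
curated window (5'-tag chemistry is stranded; this blocks antisense
contamination). Unassigned molecules stay available as a side channel, so
molecules are conserved across the stage. Read categories are assigned
once per molecule with priority TSS > exonic > intronic > outside.

QC profiles: spike-in offsets are taken from each spike-in's *median*
mapped position (robust to the true start being slightly off the
reference) and reported as percent of the exactly-mapping count; TSS
vicinity offsets are strand-oriented (positive = downstream) around
window centres within ±100 bp, with the ±50 bp fraction reported; the
gene-body profile pools molecules into 20 equal-width 5'→3' bins.

## Filtering and selection (tss_select_filter)

Each TSS gets an upstream and a downstream *reference region* of its own
width, immediately adjacent, shifted past any blocking TSS (iterating
until clear); a flank running off the chromosome start is reported
absent. Sides follow transcription direction. A TSS is removed when
either flank holds strictly more than 20% of the pooled flank + TSS
molecules — "more than 20%" is read as a strict inequality, so a TSS at
exactly 20% survives. A TSS with no molecules anywhere is retained but
flagged `untested` (a 0/0 ratio is undefined; the expression gates are
the real control for such TSSs).

The major TSS is the argmax of dataset-wide totals pooled over *all* cell
types, the minor the second — so the major TSS need not lead in any one
cell type. Exact ties break towards the TSS upstream in transcription
direction (deterministic, logged). Pair distance is measured between the
nearest interval edges; pairs at ≥ 1,000 bp are `promoter`, closer pairs
`proximal` (exactly 1 kb, which the <1 kb / >1 kb phrasing leaves open,
goes to `promoter` for a clean dichotomy). Expression gates are
inclusive: TSSs need ≥ 100 molecules dataset-wide; pairs need a mean of
≥ 0.3 (or 0.5 for the DE analysis) molecules per cell per TSS, computed
as pair total / (2 · n cells) — the same statistic used as the
correlation-vs-expression x-axis.

## Co-expression (coexpression)

Pair correlations are plain Pearson r over the cells of one cell type.
Cells at the origin (zero at both TSSs) are *included*: they are real
observations, and excluding them inflates r. Pairs with fewer than 3
cells or a zero-variance vector are reported "not computable", never as
r = 0. rpk normalization is molecules per TSS / cell total × 10,000 with
an optional cell-depth gate (2,000 molecules on real-scale data; scaled
to the synthetic depth in the bundled study). Correlation is regressed on
mean pair expression by ordinary least squares with the slope's two-sided
p. Group comparisons (proximal vs promoter; major-upstream vs
-downstream) offer both Student's t (the default) and the two-sided
Mann-Whitney U.

The whole-gene-vs-major-TSS comparison computes reproducibility
correlations two ways — across genes between two pooled random half
datasets, or between random disjoint cell pairs — using whole-gene counts
and major-TSS counts on the same cells. On synthetic data the generator's
true expressed counts additionally serve as a per-gene reference signal:
with gene-body background injected, major-TSS counts correlate better
with the true transcriptional state than whole-gene counts in essentially
all genes (noise dilution), which is the package's quantitative version
of the observation that TSS counts can be *less* noisy than gene counts.

## Usage statistics (usage_tests)

**Per-cell binomial deviation.** For each gene, every cell with ≥ 1 pair
molecule is tested with the exact two-sided binomial against p0 = pooled
major fraction of its cell type, at α = 0.05, deliberately uncorrected —
the statistic is the *percentage* of deviating cells, and the exact
test's conservativeness keeps the null rate at 1–3% (verified by
simulation at 10,000 cells). The two-sided p sums the probabilities of
all outcomes no more likely than the observed one (minimum-likelihood
convention, via `scipy.stats.binomtest`); a doubled-single-tail variant
is available as a toggle. Degenerate p0 ∈ {0, 1} yields p = 1 for
conforming cells and flags the gene.

**Bimodal split.** Cells with strictly more than 5 pair molecules are
`major_high` when major > 2 × minor, else `major_low` (equality at
exactly 2:1 goes to the low group).

**Differential usage.** Per-cell minor fractions minor/(major+minor);
cells without pair expression dropped; genes must be expressed (pair
total ≥ 1) in ≥ 20% of cells of *both* types; two-sided Mann-Whitney U
with Bonferroni over tested genes; flagged only when corrected p < 0.05
*and* |Δ mean minor fraction| ≥ 0.3 — the effect floor that keeps
huge-n trivial shifts out. The U test uses scipy's automatic method
(exact when samples are small and tie-free, tie-corrected normal
approximation otherwise): minor fractions are heavily tied, which rules
out a fixed exact-below-n rule.

**Ratio-group DE.** Genes with pooled mean strictly above 0.5 molecules
per cell across the two split groups are compared by two-sided Welch's t
with Bonferroni; fold change is larger over smaller group mean, with a
strict > 2 screen and the direction reported separately.

## Numerical and design choices

- Determinism: every stochastic step derives from a single integer seed
  through independent `numpy` child streams (annotation / counts / tags),
  and stage outputs are written with a fixed float format — one config +
  seed gives byte-identical bundles; the manifest records counts, not
  timings, for the same reason.
- Interval arithmetic (trimming, flank shifting, containment) runs on
  sorted arrays per (chrom, strand); containment uses `searchsorted`
  against disjoint curated windows.
- p-values for repeated (k, n) pairs are cached per gene; brute-force
  enumeration (n ≤ 30) is the test oracle for the binomial statistic.
- Thresholds are all exposed in `PipelineConfig` and default to the
  method's defining values; the synthetic study scales only the rpk cell
  gate (150 instead of 2,000) to its sequencing depth of ~350 TSS
  molecules per cell.
- The bundled study uses 100 genes × 250 cells for the tag-level run and
  300–500 genes × 600–1,000 ground-truth cells for the statistical
  recovery checks; these sizes were chosen to make every recovery
  property stable across seeds.

## Known limitations

- The reference filter sees only the pooled dataset; per-cell filtering
  is deliberately not offered.
- UMI collisions are left uncorrected (counts can only undercount), and
  no edit-distance UMI merging is attempted.
- The generator's uniform background cannot produce the localized
  degradation peaks that make the 20% filter bite on real data at light
  background levels.
- Exclusive coupling is implemented as an activity split rather than an
  explicit three-state promoter chain; it reproduces the anti-correlation
  signature but not switching kinetics.
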