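# alttss — alternative TSS usage in single cells

Most genes have several transcription start sites (TSSs). Bulk 5'-end
assays show *which* TSSs a tissue uses; they cannot say whether two TSSs
of one gene fire in the same single cells. `alttss` answers that question
for 5'-tag UMI single-cell RNA-seq (STRT-like): it counts mRNA molecules
at curated CAGE-style TSS windows, removes degradation-contaminated TSSs,
selects each gene's major and minor TSS, and tests whether the pair is
co-regulated — or whether a gene breaks the rule with a bimodal
major:minor ratio across cells.

The statistics, for a gene with major/minor molecule counts (k, n−k) in a
cell and cell set C:

- **Pair correlation** — Pearson r between the two TSS count vectors over
  C (counts, and rpk = counts / cell total × 10⁴), with OLS of r on mean
  pair expression and t / Mann-Whitney comparisons between proximal
  (< 1 kb) and promoter-distance (≥ 1 kb) pairs.
- **Per-cell ratio deviation** — exact two-sided binomial test of k out
  of n against p₀ = pooled major fraction over C; the per-gene statistic
  is the percentage of cells with p < 0.05 (uncorrected by design).
- **Bimodal split** — cells with > 5 pair molecules are `major_high`
  when k > 2(n−k); the groups feed a Welch-t + Bonferroni DE screen
  with a strict fold-change > 2 filter.
- **Differential usage** — per-cell minor fractions compared between two
  cell types by Mann-Whitney U with Bonferroni, flagged only when
  corrected p < 0.05 **and** |Δ mean minor fraction| ≥ 0.3.

Because the analysis needs data with known truth, the package includes a
generator: per-TSS telegraph (burst) transcription in its Beta-Poisson
steady state, with per-gene coupling modes (shared / independent /
exclusive / bimodal-ratio), lognormal cell sizes, 20% molecule capture,
positional scatter, uniform gene-body degradation background, ERCC-style
spike-ins, and UMI-duplicated read emission. See `docs/methods.md` for
the model and every threshold.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study
(100 genes, 250 cells in two cell types, two engineered usage-switch
genes, a few bimodal-ratio genes; raw data under `scratch/`, summary
tables under `results/`):

```bash
python analysis/01_simulate.py
python analysis/02_quantify.py
python analysis/03_filter_select.py
python analysis/04_coexpression.py
python analysis/05_usage_tests.py
```

which prints, among other lines:

```
840,047 reads -> 311,098 molecules
spike-in molecules mapping exactly at the 5' start: 75.3%
molecule fraction at TSSs: 0.56; within +/-50 bp of TSS centre: 0.991
TSSs past the 100-molecule gate: 168; major/minor pairs: 57; past the 0.3 molecules/cell/TSS gate: 57
mean pair correlation (counts): 0.594
mean pair correlation (rpk, 125 gated cells): 0.412
genes expressing almost only the major TSS: 48%
mean % of cells deviating from the population TSS ratio: 4.8%
most bimodal gene: G0036 (22.6% of cells deviating)
differential usage between cell types: 2/57 flagged: ['G0003', 'G0004']
```

Reading it: 5' capture is sharp (75% of spike-in molecules exactly at the
start; 99% of TSS molecules within 50 bp of the window centre); about
half the genes express essentially only their major TSS; among expressed
pairs the major and minor TSS are clearly co-regulated (mean r ≈ 0.6,
slightly lower after rpk normalization, as expected when cell size drives
part of the correlation); typical genes show only a few percent of cells
off the population major:minor ratio, while the engineered bimodal gene
stands out at ~23%; and exactly the two genes simulated with a cell-type
usage switch are flagged by the differential-usage test.

The same pipeline is scriptable via the CLI (`alttss simulate`,
`quantify`, `filter`, `coexpress`, `usagetest`, `report`, `run-all`,
`tracks`) with every threshold exposed as a config key.

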