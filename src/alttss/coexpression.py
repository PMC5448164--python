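"""Co-expression of major and minor TSSs across single cells.

All correlations are plain Pearson coefficients over the cells of one cell
type; cells with zero molecules at both TSSs of a pair stay in the
computation (they are real observations at the origin). Correlation is
related to expression by ordinary least squares of r on the pair's mean
molecules per cell per TSS, and pair groups (proximal vs promoter-distance,
major-upstream vs -downstream) are compared by Student's t or
Mann-Whitney U, both two-sided.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import TssCountMatrix

log = logging.getLogger(__name__)


def rpk_normalize(
    matrix: TssCountMatrix, min_total_molecules: int | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Per-cell normalization: molecules per TSS / cell total x 10,000.

    Cells below ``min_total_molecules`` (or with zero total) are excluded
    and returned separately. Included rows sum to exactly 10,000.
    """
    totals = matrix.cell_totals
    gate = 1 if min_total_molecules is None else max(min_total_molecules, 1)
    keep = totals >= gate
    excluded = totals.index[~keep].tolist()
    if excluded:
        log.info("rpk_normalize: excluded %d cells below %d molecules", len(excluded), gate)
    counts = matrix.counts.loc[keep]
    if counts.empty:
        log.warning("rpk_normalize: no cells pass the %d-molecule gate", gate)
        return counts.astype(float), excluded
    rpk = counts.div(totals.loc[keep], axis=0) * 10_000.0
    return rpk, excluded


def major_preference(
    matrix: TssCountMatrix, bins: int = 10
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-gene fraction of TSS molecules on the major TSS, plus histogram.

    The major TSS is the gene's argmax of dataset-wide totals among the
    matrix's (already filtered) TSS columns; genes need >= 1 TSS molecule.
    A fraction of 1.0 means exclusive major-TSS expression.
    """
    totals = matrix.counts.sum(axis=0)
    gene_of = matrix.tss.set_index("tss_id")["gene_id"]
    per_gene = totals.groupby(gene_of.reindex(totals.index)).agg(["sum", "max"])
    per_gene = per_gene.loc[per_gene["sum"] > 0]
    frac = (per_gene["max"] / per_gene["sum"]).rename("major_fraction")
    frac.index.name = "gene_id"
    edges = np.linspace(0.0, 1.0, bins + 1)
    hist, _ = np.histogram(frac.to_numpy(), bins=edges)
    histogram = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "n_genes": hist}
    )
    return frac, histogram


def pair_correlation(
    values: pd.DataFrame,
    pairs: pd.DataFrame,
    cells: pd.Index | None = None,
    normalization: str = "counts",
) -> pd.DataFrame:
    """Pearson r between major and minor TSS per gene over a cell subset.

    ``values`` is a cells x tss matrix (counts or rpk). Pairs with fewer
    than 3 cells or zero variance in either vector are emitted with
    ``computable = False`` and r = NaN — never silently as r = 0.
    """
    mat = values if cells is None else values.loc[values.index.intersection(cells)]
    rows = []
    for pair in pairs.itertuples(index=False):
        ok = pair.major_tss in mat.columns and pair.minor_tss in mat.columns
        x = mat[pair.major_tss].to_numpy(float) if ok else np.array([])
        y = mat[pair.minor_tss].to_numpy(float) if ok else np.array([])
        n = len(x)
        computable = n >= 3 and np.std(x) > 0 and np.std(y) > 0
        r = float(stats.pearsonr(x, y).statistic) if computable else np.nan
        rows.append(
            {
                "gene_id": pair.gene_id,
                "r": r,
                "n_cells": n,
                "mean_pair_expression": float((x.mean() + y.mean()) / 2) if n else np.nan,
                "pair_class": pair.pair_class,
                "major_is_upstream": pair.major_is_upstream,
                "normalization": normalization,
                "computable": computable,
            }
        )
    return pd.DataFrame(rows)


def correlation_vs_expression(pair_correlations: pd.DataFrame) -> dict:
    """OLS fit of pair correlation on mean pair expression (lm-style).

    Returns slope, intercept, the slope's two-sided p-value and n. Needs
    >= 3 computable pairs with variable expression.
    """
    d = pair_correlations.loc[pair_correlations["computable"]]
    if len(d) < 3:
        raise ValueError("correlation_vs_expression needs >= 3 computable pairs")
    x = d["mean_pair_expression"].to_numpy()
    y = d["r"].to_numpy()
    if np.std(x) == 0:
        raise ValueError("zero variance in mean pair expression")
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "p_value": float(fit.pvalue),
        "n_genes": int(len(d)),
    }


def compare_pair_groups(
    pair_correlations: pd.DataFrame,
    grouping: str = "pair_class",
    test: str = "t",
) -> dict:
    """Compare pair correlations between two groups of genes.

    ``grouping`` is ``pair_class`` (proximal vs promoter) or
    ``major_is_upstream``. Both Student's t and Mann-Whitney U are
    available, two-sided. Groups with n < 2 yield p = NaN.
    """
    if grouping not in ("pair_class", "major_is_upstream"):
        raise ValueError("grouping must be 'pair_class' or 'major_is_upstream'")
    if test not in ("t", "mannwhitney"):
        raise ValueError("test must be 't' or 'mannwhitney'")
    d = pair_correlations.loc[pair_correlations["computable"]]
    levels = sorted(d[grouping].unique(), key=str)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, found {levels}")
    g1 = d.loc[d[grouping] == levels[0], "r"].to_numpy()
    g2 = d.loc[d[grouping] == levels[1], "r"].to_numpy()
    if min(len(g1), len(g2)) < 2:
        p = np.nan
    elif test == "t":
        if np.std(g1) == 0 and np.std(g2) == 0:
            p = 1.0 if np.mean(g1) == np.mean(g2) else 0.0
        else:
            p = float(stats.ttest_ind(g1, g2).pvalue)
    else:
        p = float(stats.mannwhitneyu(g1, g2, alternative="two-sided").pvalue)
    return {
        "grouping": grouping,
        "test": test,
        "groups": {
            str(levels[0]): {"n": int(len(g1)), "mean_r": float(np.mean(g1)) if len(g1) else np.nan,
                             "sd_r": float(np.std(g1, ddof=1)) if len(g1) > 1 else np.nan},
            str(levels[1]): {"n": int(len(g2)), "mean_r": float(np.mean(g2)) if len(g2) else np.nan,
                             "sd_r": float(np.std(g2, ddof=1)) if len(g2) > 1 else np.nan},
        },
        "p_value": p,
    }


def whole_gene_counts(
    molecules: pd.DataFrame, genes: pd.DataFrame, cells: pd.Index
) -> pd.DataFrame:
    """Per-cell molecule counts over whole gene spans (strand-aware)."""
    from .quantify import _containment_lookup

    hits = _containment_lookup(
        molecules, genes[["gene_id", "chrom", "strand", "start", "end"]], stranded=True
    )
    mol = molecules.assign(gene_id=hits).dropna(subset=["gene_id"])
    counts = (
        mol.groupby(["cell_id", "gene_id"], sort=True, observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=cells, columns=genes["gene_id"], fill_value=0)
        .astype(np.int64)
    )
    counts.index.name = "cell_id"
    return counts


def per_gene_correlation(a: pd.DataFrame, b: pd.DataFrame) -> pd.Series:
    """Column-wise Pearson r between two aligned cells x genes matrices."""
    common = a.columns.intersection(b.columns)
    x = a[common].to_numpy(float)
    y = b.loc[a.index, common].to_numpy(float)
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    denom = np.sqrt((x**2).sum(axis=0) * (y**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x * y).sum(axis=0) / denom
    return pd.Series(r, index=common, name="r")


def whole_gene_vs_major_tss(
    gene_counts: pd.DataFrame,
    major_counts: pd.DataFrame,
    mode: str = "pooled",
    n_pairs: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Reproducibility correlations from whole-gene vs major-TSS counts.

    Both inputs are cells x genes matrices over the same cells (columns of
    ``major_counts`` are the genes' major-TSS counts). ``pooled`` splits the
    cells into two random halves, sums each half, and correlates the two
    pools across genes — once per normalization. ``cell_pairs`` correlates
    individual random disjoint cell pairs across genes. Returns one row per
    comparison with ``r_whole_gene`` and ``r_major_tss``.
    """
    rng = np.random.default_rng(seed)
    cells = gene_counts.index.to_numpy()
    common = gene_counts.columns.intersection(major_counts.columns)
    g = gene_counts[common]
    m = major_counts[common]

    def _r(x: np.ndarray, y: np.ndarray) -> float:
        if np.std(x) == 0 or np.std(y) == 0:
            return np.nan
        return float(stats.pearsonr(x, y).statistic)

    rows = []
    if mode == "pooled":
        perm = rng.permutation(len(cells))
        half = len(cells) // 2
        a, b = cells[perm[:half]], cells[perm[half : 2 * half]]
        rows.append(
            {
                "comparison": "pooled_halves",
                "r_whole_gene": _r(g.loc[a].sum(axis=0).to_numpy(), g.loc[b].sum(axis=0).to_numpy()),
                "r_major_tss": _r(m.loc[a].sum(axis=0).to_numpy(), m.loc[b].sum(axis=0).to_numpy()),
                "n_cells_per_side": half,
            }
        )
    elif mode == "cell_pairs":
        perm = rng.permutation(len(cells))
        n_pairs = min(n_pairs, len(cells) // 2)
        for k in range(n_pairs):
            c1, c2 = cells[perm[2 * k]], cells[perm[2 * k + 1]]
            rows.append(
                {
                    "comparison": f"{c1}|{c2}",
                    "r_whole_gene": _r(g.loc[c1].to_numpy(), g.loc[c2].to_numpy()),
                    "r_major_tss": _r(m.loc[c1].to_numpy(), m.loc[c2].to_numpy()),
                    "n_cells_per_side": 1,
                }
            )
    else:
        raise ValueError("mode must be 'pooled' or 'cell_pairs'")
    return pd.DataFrame(rows)
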