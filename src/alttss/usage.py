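"""Ratio-based statistics on major/minor TSS usage.

* Per-cell binomial deviation: for each gene, every cell expressing the
  pair is tested (exact two-sided binomial, minimum-likelihood convention)
  against the population major fraction of its cell type — uncorrected, as
  a descriptive per-cell statistic.
* Bimodal split: cells with > 5 pair molecules are divided at a 2:1
  major:minor ratio (equality goes to the low group).
* Differential usage between cell types: Mann-Whitney on per-cell minor
  fractions with Bonferroni correction plus a 0.3 effect-size floor.
* Ratio-group differential expression: Welch's t with Bonferroni between
  the split groups, with a strict > 2 fold-change screen.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def binom_two_sided(k: int, n: int, p0: float, convention: str = "minlike") -> float:
    """Exact two-sided binomial p-value.

    ``minlike`` sums the probabilities of all outcomes no more likely than
    the observed one (the convention of scipy's binomtest); ``double``
    doubles the smaller one-sided tail, capped at 1.
    """
    if convention == "minlike":
        return float(stats.binomtest(k, n, p0).pvalue)
    if convention == "double":
        lo = stats.binom.cdf(k, n, p0)
        hi = stats.binom.sf(k - 1, n, p0)
        return float(min(1.0, 2.0 * min(lo, hi)))
    raise ValueError("convention must be 'minlike' or 'double'")


@dataclass
class BinomialDeviationResult:
    gene_id: str
    p0: float
    per_cell: pd.DataFrame  # cell_id, k, n, p_value, deviating
    percent_deviating: float
    n_eligible: int
    degenerate_p0: bool


def binomial_deviation(
    major: pd.Series,
    minor: pd.Series,
    alpha: float = 0.05,
    gene_id: str = "",
    p0: float | None = None,
    convention: str = "minlike",
) -> BinomialDeviationResult:
    """Fraction of cells deviating from the population major:minor ratio.

    ``major`` and ``minor`` are per-cell molecule counts aligned on cell id.
    The success probability is the pooled major fraction over all cells
    (computed from the same vectors unless ``p0`` is given); eligible cells
    express >= 1 pair molecule; p-values are uncorrected by design.
    """
    major = major.astype(int)
    minor = minor.reindex(major.index).fillna(0).astype(int)
    total = major + minor
    if p0 is None:
        pooled = int(total.sum())
        if pooled == 0:
            raise ValueError("p0 not computable: no pair molecules in any cell")
        p0 = float(major.sum() / pooled)
    degenerate = p0 in (0.0, 1.0)
    if degenerate:
        log.warning("binomial_deviation[%s]: degenerate p0=%g", gene_id, p0)

    eligible = total >= 1
    ks = major.loc[eligible].to_numpy()
    ns = total.loc[eligible].to_numpy()
    if degenerate:
        conforming = ks == (ns if p0 == 1.0 else 0)
        ps = np.where(conforming, 1.0, 0.0)
    else:
        # cells share few distinct (k, n) pairs; compute each once
        cache = {
            (k, n): binom_two_sided(k, n, p0, convention)
            for k, n in set(zip(ks.tolist(), ns.tolist()))
        }
        ps = np.array([cache[(k, n)] for k, n in zip(ks.tolist(), ns.tolist())])
    per_cell = pd.DataFrame(
        {
            "cell_id": major.index[eligible],
            "k": ks,
            "n": ns,
            "p_value": ps,
            "deviating": ps < alpha,
        }
    )
    n_eligible = int(eligible.sum())
    percent = 100.0 * per_cell["deviating"].mean() if n_eligible else np.nan
    return BinomialDeviationResult(
        gene_id=gene_id,
        p0=p0,
        per_cell=per_cell,
        percent_deviating=float(percent),
        n_eligible=n_eligible,
        degenerate_p0=degenerate,
    )


def bimodal_split(
    major: pd.Series,
    minor: pd.Series,
    min_total: int = 5,
    ratio: float = 2.0,
) -> pd.DataFrame:
    """Split cells by major:minor ratio; eligibility is strictly > min_total.

    Cells with major + minor > ``min_total`` molecules are labelled
    ``major_high`` when major > ratio x minor and ``major_low`` otherwise
    (equality at exactly ratio:1 goes to ``major_low``).
    """
    major = major.astype(int)
    minor = minor.reindex(major.index).fillna(0).astype(int)
    total = major + minor
    eligible = total > min_total
    label = np.where(major > ratio * minor, "major_high", "major_low")
    return pd.DataFrame(
        {
            "cell_id": major.index,
            "pair_total": total.to_numpy(),
            "eligible": eligible.to_numpy(),
            "group": np.where(eligible, label, ""),
        }
    )


def minor_fractions(major: pd.Series, minor: pd.Series) -> pd.Series:
    """Per-cell minor/(major+minor); cells with no pair expression are NaN."""
    major = major.astype(float)
    minor = minor.reindex(major.index).fillna(0).astype(float)
    total = major + minor
    with np.errstate(invalid="ignore", divide="ignore"):
        f = minor / total
    return f.where(total > 0)


def differential_usage(
    major_a: pd.DataFrame,
    minor_a: pd.DataFrame,
    major_b: pd.DataFrame,
    minor_b: pd.DataFrame,
    alpha: float = 0.05,
    min_expressed_frac: float = 0.20,
    min_delta: float = 0.3,
) -> pd.DataFrame:
    """Differential minor-fraction usage between two cell types.

    Inputs are cells x genes matrices of major- and minor-TSS counts for
    each cell type (columns aligned on gene). Per gene: cells without pair
    expression are dropped; the gene must be expressed in >= 20% of cells
    in BOTH types; the two minor-fraction samples are compared by a
    two-sided Mann-Whitney U (scipy method="auto": exact when small and
    tie-free, tie-corrected normal approximation otherwise), Bonferroni-
    corrected over tested genes; a gene is flagged only when the corrected
    p < alpha AND the absolute difference in mean minor fraction >= 0.3.
    """
    genes = major_a.columns.intersection(major_b.columns)
    rows = []
    for gene in genes:
        fa = minor_fractions(major_a[gene], minor_a[gene]).dropna()
        fb = minor_fractions(major_b[gene], minor_b[gene]).dropna()
        frac_a = len(fa) / len(major_a) if len(major_a) else 0.0
        frac_b = len(fb) / len(major_b) if len(major_b) else 0.0
        if frac_a < min_expressed_frac or frac_b < min_expressed_frac:
            continue
        if len(fa) < 2 or len(fb) < 2:
            log.info("differential_usage: %s skipped (<2 expressing cells)", gene)
            continue
        if fa.nunique() == 1 and fb.nunique() == 1 and fa.iloc[0] == fb.iloc[0]:
            p_raw = 1.0
        else:
            p_raw = float(
                stats.mannwhitneyu(fa, fb, alternative="two-sided", method="auto").pvalue
            )
        rows.append(
            {
                "gene_id": gene,
                "n_cells_a": len(fa),
                "n_cells_b": len(fb),
                "mean_minor_frac_a": float(fa.mean()),
                "mean_minor_frac_b": float(fb.mean()),
                "delta": float(abs(fa.mean() - fb.mean())),
                "p_raw": p_raw,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "n_cells_a", "n_cells_b", "mean_minor_frac_a",
            "mean_minor_frac_b", "delta", "p_raw",
        ],
    )
    m = len(result)
    result["p_bonferroni"] = np.minimum(result["p_raw"] * m, 1.0) if m else []
    result["flagged"] = (result["p_bonferroni"] < alpha) & (result["delta"] >= min_delta)
    return result


def ratio_group_de(
    counts: pd.DataFrame,
    split: pd.DataFrame,
    min_mean: float = 0.5,
    fold_change: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch's t differential expression between ratio-split cell groups.

    ``counts`` is cells x genes (whole-gene or TSS counts); ``split`` comes
    from :func:`bimodal_split`. Genes with pooled mean expression strictly
    above ``min_mean`` over the two groups are tested two-sided with
    Bonferroni correction; fold change is the larger group mean over the
    smaller, passing the screen only when strictly > ``fold_change``.
    Zero-variance-in-both-groups genes are skipped (logged).
    """
    eligible = split.loc[split["eligible"]]
    high = eligible.loc[eligible["group"] == "major_high", "cell_id"]
    low = eligible.loc[eligible["group"] == "major_low", "cell_id"]
    if len(high) < 2 or len(low) < 2:
        raise ValueError("both ratio groups need >= 2 cells")
    a = counts.loc[counts.index.intersection(high)]
    b = counts.loc[counts.index.intersection(low)]
    pooled_mean = pd.concat([a, b]).mean(axis=0)
    tested = pooled_mean.index[pooled_mean > min_mean]

    rows = []
    n_skipped = 0
    for gene in tested:
        x, y = a[gene].to_numpy(float), b[gene].to_numpy(float)
        if np.std(x) == 0 and np.std(y) == 0:
            n_skipped += 1
            continue
        p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
        mx, my = float(x.mean()), float(y.mean())
        hi, lo_ = max(mx, my), min(mx, my)
        fc = np.inf if lo_ == 0 else hi / lo_
        rows.append(
            {
                "gene_id": gene,
                "mean_major_high": mx,
                "mean_major_low": my,
                "fold_change": fc,
                "direction": "major_high" if mx >= my else "major_low",
                "p_raw": p,
            }
        )
    if n_skipped:
        log.info("ratio_group_de: skipped %d zero-variance genes", n_skipped)
    result = pd.DataFrame(
        rows,
        columns=["gene_id", "mean_major_high", "mean_major_low", "fold_change",
                 "direction", "p_raw"],
    )
    m = len(result)
    result["p_bonferroni"] = np.minimum(result["p_raw"] * m, 1.0) if m else []
    result["significant"] = result["p_bonferroni"] < alpha
    result["passes_fc"] = result["fold_change"] > fold_change
    return result
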