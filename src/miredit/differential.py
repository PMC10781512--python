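"""Two-group differential-editing statistics and correlation diagnostics.

The group comparison is the unpaired two-tailed Welch t-test per site, with
Benjamini-Hochberg step-up FDR control across all testable sites; a site is
differentially edited when its adjusted p falls below alpha. Companion
utilities fit the edited-vs-total abundance regression (to check that a
drop in editing is not an abundance artifact), compute median-of-ratios
size factors, and Spearman rank correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    testable: bool


def welch_t_test(x, y) -> WelchResult:
    """Unpaired two-tailed t-test with Welch's correction.

    Missing values are dropped. Degenerate cases: fewer than two non-missing
    observations in either group, or zero variance in both groups with
    unequal means, are flagged untestable (no p); zero variance in both
    groups with equal means yields t=0, p=1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        return WelchResult(math.nan, math.nan, math.nan, False)
    if x.max() == x.min() and y.max() == y.min():  # both groups constant
        if x[0] == y[0]:
            return WelchResult(0.0, float(len(x) + len(y) - 2), 1.0, True)
        return WelchResult(math.nan, math.nan, math.nan, False)
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue), True)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone on the sorted raw p's, capped at 1, stable under permutation
    of the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_editing(
    matrix, design: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Welch t-test per retained site between the two design groups, BH-FDR.

    ``matrix`` is a SampleEditingMatrix (or a levels DataFrame with sites as
    index and samples as columns). Untestable sites are kept in the output
    with NaN statistics but excluded from the BH family. Returns a table in
    the ``differential`` schema with per-group mean levels.
    """
    levels = matrix.levels if hasattr(matrix, "levels") else matrix
    groups = design.groupby("group")["sample_id"].apply(list)
    if len(groups) != 2:
        raise ValueError(f"design must have exactly two groups, found {len(groups)}")
    (g1, samples1), (g2, samples2) = sorted(groups.items())
    missing = (set(samples1) | set(samples2)) - set(levels.columns)
    if missing:
        raise ValueError(f"design samples absent from matrix: {sorted(missing)}")

    rows = []
    for site in levels.index:
        x = levels.loc[site, samples1].to_numpy(dtype=float)
        y = levels.loc[site, samples2].to_numpy(dtype=float)
        res = welch_t_test(x, y)
        mature_id, pos = str(site).rsplit(":", 1) if ":" in str(site) else (str(site), "0")
        rows.append(
            {
                "site": site,
                "mature_id": mature_id,
                "position": int(pos),
                f"mean_{g1}": np.nanmean(x) if np.any(~np.isnan(x)) else np.nan,
                f"mean_{g2}": np.nanmean(y) if np.any(~np.isnan(y)) else np.nan,
                "welch_t": res.t,
                "welch_df": res.df,
                "p_raw": res.p,
                "testable": res.testable,
            }
        )
    out = pd.DataFrame(rows)
    out["p_bh"] = np.nan
    if len(out):
        testable = out["testable"].to_numpy()
        if testable.any():
            out.loc[testable, "p_bh"] = bh_adjust(out.loc[testable, "p_raw"])
    out["significant"] = out["p_bh"] < alpha
    return out


@dataclass
class ResidualReport:
    """OLS fit of edited abundance on total abundance with residuals."""

    table: pd.DataFrame  # sample_id, edited, total, fitted, residual
    slope: float
    intercept: float
    pearson_r: float
    pearson_p: float
    transform: str
    degenerate: bool = False


def _transform_values(values: np.ndarray, transform: str, library_sizes) -> np.ndarray:
    if transform == "linear":
        return values.astype(float)
    if transform == "log2_cpm_plus1":
        lib = np.asarray(library_sizes, dtype=float)
        cpm = values / lib * 1e6
        return np.log2(cpm + 1.0)
    raise ValueError(f"unknown transform {transform!r}")


def abundance_residuals(
    edited_counts,
    total_counts,
    transform: str = "log2_cpm_plus1",
    library_sizes=None,
    sample_ids=None,
) -> ResidualReport:
    """Regress per-sample edited abundance on total abundance.

    Detects whether the edited form deviates from what overall abundance
    predicts: samples far above the fitted line carry more editing than
    their miRNA abundance explains (residual 0 = perfect-fit line). The
    default transform is log2(CPM+1); library sizes default to the total
    counts themselves when not supplied.
    """
    edited = np.asarray(edited_counts, dtype=float)
    total = np.asarray(total_counts, dtype=float)
    if edited.shape != total.shape:
        raise ValueError("edited and total vectors must have equal length")
    if len(edited) < 3:
        raise ValueError("need at least 3 paired samples")
    if library_sizes is None:
        library_sizes = total if transform == "log2_cpm_plus1" else np.ones_like(total)
    xe = _transform_values(edited, transform, library_sizes)
    xt = _transform_values(total, transform, library_sizes)
    if sample_ids is None:
        sample_ids = [f"s{i+1}" for i in range(len(edited))]

    if np.allclose(xt, xt[0]):
        table = pd.DataFrame(
            {"sample_id": sample_ids, "edited": xe, "total": xt,
             "fitted": np.nan, "residual": np.nan}
        )
        return ResidualReport(table, math.nan, math.nan, math.nan, math.nan,
                              transform, degenerate=True)

    fit = stats.linregress(xt, xe)
    fitted = fit.intercept + fit.slope * xt
    residuals = xe - fitted
    table = pd.DataFrame(
        {"sample_id": sample_ids, "edited": xe, "total": xt,
         "fitted": fitted, "residual": residuals}
    )
    return ResidualReport(
        table, float(fit.slope), float(fit.intercept),
        float(fit.rvalue), float(fit.pvalue), transform,
    )


def median_of_ratios_normalize(
    count_matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios (DESeq2-style) size factors and normalized counts.

    The size factor of a sample is the median, over genes with all-positive
    counts, of that sample's count divided by the gene's geometric mean
    across samples. Normalized counts are raw counts over the size factor.
    """
    counts = count_matrix.astype(float)
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no gene with all-positive counts; size factors undefined")
    ref = counts.loc[all_positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref).sub(log_geomean, axis=0)
    size_factors = np.exp(ratios.median(axis=0))
    normalized = counts.div(size_factors, axis=1)
    return normalized, size_factors


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation (Pearson on mid-ranks; NaN if degenerate)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors with at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    return float(stats.spearmanr(x, y).statistic)
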