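"""A->G editing-site calling from per-position base tallies.

A candidate site is a reference adenosine within a mature arm showing G in
the reads. The editing level at a site is k/n: reads carrying G over total
reads covering the position. Candidates are filtered by three rules:

1. at least ``min_edited_reads`` edited reads summed across samples
   (a per-sample variant is available);
2. the G count is inconsistent with sequencing error in at least
   ``min_samples_pass`` samples, judged by the upper tail of
   Binomial(n, error_rate);
3. the mean editing level across samples is at least ``min_mean_level``
   (low-level editing, below ~10%, is unlikely to be biologically
   meaningful and is removed before group comparison).

Non-A->G mismatches are tallied in a diagnostics table but never treated
as editing candidates (A-to-I is the only chemistry considered).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SiteFilterParams:
    error_rate: float = 0.01
    error_alpha: float = 0.05
    min_edited_reads: int = 10
    min_mean_level: float = 0.10
    min_samples_pass: int = 1
    min_edited_scope: str = "sum"  # "sum" across samples or "per_sample"

    def __post_init__(self) -> None:
        if not (0.0 < self.error_rate < 1.0):
            raise ValueError("error_rate must be in (0, 1)")
        if not (0.0 < self.error_alpha <= 1.0):
            raise ValueError("error_alpha must be in (0, 1]")
        if self.min_edited_reads < 0:
            raise ValueError("min_edited_reads must be >= 0")
        if not (0.0 <= self.min_mean_level <= 1.0):
            raise ValueError("min_mean_level must be in [0, 1]")
        if self.min_edited_scope not in ("sum", "per_sample"):
            raise ValueError("min_edited_scope must be 'sum' or 'per_sample'")


def compute_editing_level(k: int, n: int) -> float:
    """Editing level k/n; NaN (missing) when the position is uncovered."""
    if k < 0 or (n >= 0 and k > n):
        raise ValueError(f"invalid counts k={k}, n={n} (need 0 <= k <= n)")
    if n == 0:
        return float("nan")
    return k / n


def binomial_error_pvalue(k, n, p: float):
    """Upper-tail P(X >= k) for X ~ Binomial(n, p), the error-model test.

    Uses the survival function, numerically stable for large n. Accepts
    scalars or arrays.
    """
    k_arr = np.asarray(k)
    n_arr = np.asarray(n)
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    if np.any(k_arr < 0) or np.any(k_arr > n_arr):
        raise ValueError("need 0 <= k <= n")
    out = stats.binom.sf(k_arr - 1, n_arr, p)
    if np.isscalar(k) and np.isscalar(n):
        return float(out)
    return out


def call_sites(
    counts: pd.DataFrame,
    params: SiteFilterParams = SiteFilterParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call A->G editing sites from a ``counts``-schema table.

    Returns ``(sites, diagnostics)``: the per-sample table of retained
    sites (``sites`` schema: sample_id, mature_id, position, ref, alt, k,
    n, level) and a diagnostics table of all non-reference substitutions
    with their summed counts and whether they are A->G candidates.

    The three retention filters commute: each is a per-site predicate
    computed from the full cross-sample table, so applying them in any
    order yields the same retained set.
    """
    required = {"sample_id", "mature_id", "position", "ref_base", "A", "C", "G", "U"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns {sorted(missing)}")

    df = counts.copy()
    df["n"] = df[["A", "C", "G", "U"]].sum(axis=1)

    # diagnostics: every substitution away from the reference base
    diag_rows = []
    for alt in "ACGU":
        sub = df[df["ref_base"] != alt]
        agg = sub.groupby(["mature_id", "position", "ref_base"], sort=True)[alt].sum()
        for (mid, pos, ref), cnt in agg.items():
            if cnt > 0:
                diag_rows.append(
                    (mid, pos, ref, alt, int(cnt), bool(ref == "A" and alt == "G"))
                )
    diagnostics = pd.DataFrame(
        diag_rows,
        columns=["mature_id", "position", "ref", "alt", "total_count", "is_adar_candidate"],
    ).sort_values(["mature_id", "position", "alt"], ignore_index=True)

    cand = df[df["ref_base"] == "A"].copy()
    if cand.empty:
        sites = pd.DataFrame(
            columns=["sample_id", "mature_id", "position", "ref", "alt", "k", "n", "level"]
        )
        return sites, diagnostics
    cand["k"] = cand["G"]
    with np.errstate(invalid="ignore", divide="ignore"):
        cand["level"] = np.where(cand["n"] > 0, cand["k"] / cand["n"], np.nan)
    covered = cand["n"] > 0
    pvals = np.ones(len(cand))
    pvals[covered.to_numpy()] = binomial_error_pvalue(
        cand.loc[covered, "k"].to_numpy(),
        cand.loc[covered, "n"].to_numpy(),
        params.error_rate,
    )
    cand["error_pass"] = (pvals < params.error_alpha) & covered.to_numpy()

    grp = cand.groupby(["mature_id", "position"], sort=True)
    k_sum = grp["k"].sum()
    k_min = grp["k"].min()
    mean_level = grp["level"].mean()  # mean over covered samples
    n_pass = grp["error_pass"].sum()

    if params.min_edited_scope == "sum":
        rule_reads = k_sum >= params.min_edited_reads
    else:
        rule_reads = k_min >= params.min_edited_reads
    rule_error = n_pass >= params.min_samples_pass
    rule_level = mean_level >= params.min_mean_level
    retained = rule_reads & rule_error & rule_level
    keep = retained[retained].index

    sites = cand.set_index(["mature_id", "position"]).loc[
        cand.set_index(["mature_id", "position"]).index.isin(set(keep))
    ].reset_index()
    sites["ref"] = "A"
    sites["alt"] = "G"
    sites = sites[
        ["sample_id", "mature_id", "position", "ref", "alt", "k", "n", "level"]
    ].sort_values(["mature_id", "position", "sample_id"], ignore_index=True)
    return sites, diagnostics


@dataclass
class SampleEditingMatrix:
    """Cross-sample editing levels with the underlying k and n matrices.

    Rows are retained sites (index "mature_id:position"), columns are
    samples in design order. Cells with n=0 are missing (NaN), not 0.
    """

    levels: pd.DataFrame
    k: pd.DataFrame
    n: pd.DataFrame

    @property
    def sites(self) -> list[str]:
        return list(self.levels.index)

    def site_position(self, site: str) -> tuple[str, int]:
        mature_id, pos = site.rsplit(":", 1)
        return mature_id, int(pos)

    def to_table(self) -> pd.DataFrame:
        out = self.levels.copy()
        out.insert(0, "site", out.index)
        return out.reset_index(drop=True)


def build_matrix(sites: pd.DataFrame, design: pd.DataFrame) -> SampleEditingMatrix:
    """Assemble the site x sample editing-level matrix from a sites table.

    Samples absent from a site's rows (or covered by zero reads) get NaN.
    Duplicated (site, sample) entries are an error.
    """
    samples = list(design["sample_id"])
    if sites.empty:
        empty = pd.DataFrame(columns=samples)
        return SampleEditingMatrix(empty, empty.copy(), empty.copy())
    df = sites.copy()
    df["site"] = df["mature_id"].astype(str) + ":" + df["position"].astype(str)
    if df.duplicated(["site", "sample_id"]).any():
        dup = df[df.duplicated(["site", "sample_id"])].iloc[0]
        raise ValueError(
            f"duplicated entry for site {dup['site']} sample {dup['sample_id']}"
        )
    unknown = set(df["sample_id"]) - set(samples)
    if unknown:
        raise ValueError(f"sites table has samples absent from design: {sorted(unknown)}")

    def pivot(col):
        wide = df.pivot(index="site", columns="sample_id", values=col)
        return wide.reindex(columns=samples)

    levels, k, n = pivot("level"), pivot("k"), pivot("n")
    levels = levels.where(n > 0)  # n=0 means missing, never 0
    return SampleEditingMatrix(levels, k, n)
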