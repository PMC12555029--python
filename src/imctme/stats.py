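"""Cohort-level aggregation and group comparisons.

Measurements are computed per ROI, averaged to one value per sample (the
unit of inference), and compared between groups with the two-sided
Wilcoxon rank-sum test: exact by enumeration of the rank-sum distribution
for small tie-free samples, otherwise a tie- and continuity-corrected
normal approximation.  Benjamini-Hochberg adjustment is available per
named comparison family but comparisons default to unadjusted p values
(alpha 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, DataError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-ROI -> per-sample aggregation
# ---------------------------------------------------------------------------

def phenotype_fraction_per_roi(cells: pd.DataFrame, phenotype: str,
                               phenotype_col: str = "phenotype",
                               compartment: str | None = None) -> pd.DataFrame:
    """Fraction of cells of *phenotype* per ROI.

    Normalization denominator: all (non-excluded) cells of the ROI, or the
    cells of one *compartment* when given.  ROIs with a zero denominator
    yield a missing value (excluded from sample means, logged).
    """
    df = cells
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    rows = []
    for roi_id, sub in df.groupby("roi_id", sort=True):
        denom_cells = sub if compartment is None else \
            sub[sub["compartment"] == compartment]
        denom = len(denom_cells)
        num = int((denom_cells[phenotype_col] == phenotype).sum())
        if denom == 0:
            log.warning("ROI %s: empty denominator for %r fraction; value "
                        "treated as missing", roi_id, phenotype)
            value = np.nan
        else:
            value = num / denom
        rows.append({"roi_id": roi_id,
                     "sample_id": sub["sample_id"].iloc[0],
                     "value": value, "numerator": num, "denominator": denom})
    return pd.DataFrame(rows)


def roi_to_sample_means(roi_values: pd.DataFrame, value_col: str = "value",
                        measurement: str = "") -> pd.DataFrame:
    """Average per-ROI values to one mean per sample.

    Missing ROI values are excluded from the mean; the result is invariant
    to ROI ordering.  Returns columns (sample_id, measurement, value,
    n_rois).
    """
    rows = []
    for sample_id, sub in roi_values.groupby("sample_id", sort=True):
        vals = sub[value_col].dropna()
        rows.append({
            "sample_id": sample_id,
            "measurement": measurement,
            "value": float(vals.mean()) if len(vals) else np.nan,
            "n_rois": int(len(vals)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    measurement: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float            # rank-sum W of group A (midranks)
    p_value: float
    mode: str                   # "exact" | "normal-approx"
    p_adjusted: float | None = None


def _ranksum_distribution(n_a: int, n_total: int) -> np.ndarray:
    """Exact null distribution of the rank-sum of a size-n_a subset of
    ranks 1..n_total: counts[w] = #subsets with sum w (dynamic program)."""
    max_w = n_total * (n_total + 1) // 2
    counts = np.zeros((n_a + 1, max_w + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for r in range(1, n_total + 1):
        for k in range(min(r, n_a), 0, -1):
            counts[k, r:] += counts[k - 1, :-r]
    return counts[n_a]


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float],
                      mode: str = "auto",
                      measurement: str = "", group_a: str = "A",
                      group_b: str = "B") -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``mode='exact'`` enumerates the rank-sum null distribution (requires
    tie-free data); ``'normal-approx'`` uses the tie-corrected normal
    approximation with continuity correction; ``'auto'`` picks exact when
    nA + nB <= 12 and there are no ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 1 or len(b) < 1:
        raise DataError("both groups need at least one non-missing value")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    ranks = sps.rankdata(pooled)          # midranks
    w = float(ranks[: len(a)].sum())
    if np.ptp(pooled) == 0:
        log.warning("degenerate comparison: all values identical; p = 1")
        return ComparisonResult(measurement, group_a, group_b, len(a), len(b),
                                w, 1.0, "degenerate")
    if mode == "auto":
        mode = "exact" if (len(pooled) <= 12 and not has_ties) else "normal-approx"
    if mode == "exact":
        if has_ties:
            raise ConfigurationError(
                "exact mode requires tie-free data; use normal-approx")
        dist = _ranksum_distribution(len(a), len(pooled))
        total = dist.sum()
        wi = int(round(w))
        p_low = dist[: wi + 1].sum() / total
        p_high = dist[wi:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return ComparisonResult(measurement, group_a, group_b, len(a), len(b),
                                w, float(p), "exact")
    if mode == "normal-approx":
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        return ComparisonResult(measurement, group_a, group_b, len(a), len(b),
                                w, float(res.pvalue), "normal-approx")
    raise ConfigurationError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# multiple-testing adjustment
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (input order kept)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p values must lie in (0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# convenience: compare a set of measurements between two groups
# ---------------------------------------------------------------------------

def compare_groups(sample_values: pd.DataFrame, meta: pd.DataFrame,
                   group_col: str, mode: str = "auto",
                   adjust: bool = False) -> pd.DataFrame:
    """Wilcoxon comparisons of each measurement between the two levels of
    *group_col* (sample-level values; missing samples dropped, never
    imputed).  BH adjustment across the measurement family on request."""
    merged = sample_values.merge(meta[["sample_id", group_col]], on="sample_id")
    levels = sorted(merged[group_col].dropna().unique())
    if len(levels) != 2:
        raise DataError(f"{group_col!r} must have exactly 2 levels, got {levels}")
    rows = []
    for measurement, sub in merged.groupby("measurement", sort=True):
        va = sub.loc[sub[group_col] == levels[0], "value"].to_numpy()
        vb = sub.loc[sub[group_col] == levels[1], "value"].to_numpy()
        res = wilcoxon_rank_sum(va, vb, mode=mode, measurement=measurement,
                                group_a=str(levels[0]), group_b=str(levels[1]))
        rows.append(res)
    out = pd.DataFrame([r.__dict__ for r in rows])
    if adjust and len(out):
        out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    return out


def proportion_pct(count: int, total: int) -> float:
    """Percentage share count/total*100 (used for cohort bookkeeping
    tables such as subtype or mutation prevalence)."""
    if total <= 0:
        raise DataError("total must be positive")
    if not 0 <= count <= total:
        raise DataError("need 0 <= count <= total")
    return 100.0 * count / total


def mean_per_unit(total: float, n_units: int) -> float:
    """Mean count per unit (e.g., segmented cells per image)."""
    if n_units <= 0:
        raise DataError("n_units must be positive")
    return total / n_units


def boxplot_by_group(sample_values: pd.DataFrame, meta: pd.DataFrame,
                     group_col: str, path) -> None:
    """Sample-level dot + box figure per measurement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    merged = sample_values.merge(meta[["sample_id", group_col]], on="sample_id")
    measurements = sorted(merged["measurement"].unique())
    fig, axes = plt.subplots(1, max(len(measurements), 1),
                             figsize=(3 * max(len(measurements), 1), 3.2),
                             squeeze=False)
    for ax, m in zip(axes[0], measurements):
        sub = merged[merged["measurement"] == m]
        levels = sorted(sub[group_col].dropna().unique())
        data = [sub.loc[sub[group_col] == g, "value"].dropna() for g in levels]
        ax.boxplot(data, tick_labels=levels)
        for i, vals in enumerate(data, start=1):
            jitter = (np.arange(len(vals)) - len(vals) / 2) * 0.02
            ax.plot(np.full(len(vals), i) + jitter, vals, "o", ms=3, alpha=0.7)
        ax.set_title(m, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
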