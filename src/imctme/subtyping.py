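"""Microenvironment subtyping by the FOXL2+COL1A1+ cell fraction.

The per-sample statistic is f = (# FOXL2+COL1A1+ cells) / (# all FOXL2+
cells), pooled over the sample's ROIs (cell-weighted, not ROI-averaged,
because the statistic is defined on cells).  Across a cohort the fractions
are bimodal; the classification threshold is found by the valley method:
a Gaussian kernel density (Silverman bandwidth, boundary reflection at 0
and 1, uniform grid) is evaluated and the threshold is the density minimum
between its two highest modes.  Samples with f >= threshold are called
AGCT-2 (collagen-intermixed), the rest AGCT-1 (collagen-depleted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, NoValleyError

log = logging.getLogger(__name__)

AGCT1 = "AGCT-1"
AGCT2 = "AGCT-2"

FOXL2_CLASSES = ("FOXL2+COL1A1-", "FOXL2+COL1A1+")


# ---------------------------------------------------------------------------
# fraction statistic
# ---------------------------------------------------------------------------

def foxl2_col1a1_fraction(cells: pd.DataFrame,
                          phenotype_col: str = "phenotype"
                          ) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample FOXL2+COL1A1+ fraction (pooled over ROIs).

    Returns ``(per_sample_fractions, per_roi_diagnostics)``.  Raises
    :class:`DataError` naming any sample without FOXL2+ cells.
    """
    if phenotype_col not in cells.columns:
        raise DataError(f"cells lack a {phenotype_col!r} column; run phenotyping")
    is_fox = cells[phenotype_col].isin(FOXL2_CLASSES)
    is_fc = cells[phenotype_col] == "FOXL2+COL1A1+"
    per_sample_fox = is_fox.groupby(cells["sample_id"]).sum()
    empty = per_sample_fox[per_sample_fox == 0]
    if len(empty):
        raise DataError(
            f"sample(s) without FOXL2+ cells: {list(empty.index)}; "
            "the fraction is undefined")
    per_sample = (is_fc.groupby(cells["sample_id"]).sum()
                  / per_sample_fox).rename("fraction")
    roi_fox = is_fox.groupby(cells["roi_id"]).sum()
    roi_fc = is_fc.groupby(cells["roi_id"]).sum()
    per_roi = pd.DataFrame({
        "roi_id": roi_fox.index,
        "n_foxl2": roi_fox.to_numpy(),
        "n_foxl2_col1a1": roi_fc.to_numpy(),
    })
    with np.errstate(invalid="ignore"):
        per_roi["fraction"] = np.where(
            per_roi["n_foxl2"] > 0,
            per_roi["n_foxl2_col1a1"] / per_roi["n_foxl2"], np.nan)
    sample_of = cells.drop_duplicates("roi_id").set_index("roi_id")["sample_id"]
    per_roi["sample_id"] = per_roi["roi_id"].map(sample_of)
    return per_sample, per_roi


# ---------------------------------------------------------------------------
# valley threshold
# ---------------------------------------------------------------------------

@dataclass
class ValleyResult:
    threshold: float
    mode_locations: tuple[float, float]   # (lower, upper)
    mode_heights: tuple[float, float]
    valley_density: float
    bandwidth: float
    grid: np.ndarray
    density: np.ndarray


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-1 / 5)


def _reflected_kde(x: np.ndarray, bandwidth: float, grid: np.ndarray) -> np.ndarray:
    """Gaussian KDE on [0, 1] with boundary reflection at both edges."""
    data = np.concatenate([x, -x, 2.0 - x])     # reflect at 0 and at 1
    z = (grid[:, None] - data[None, :]) / bandwidth
    dens = np.exp(-0.5 * z ** 2).sum(axis=1)
    dens /= len(x) * bandwidth * np.sqrt(2 * np.pi)
    return dens


def _local_maxima(density: np.ndarray) -> np.ndarray:
    """Indices of local maxima (plateaus contribute their first index;
    boundary points count when they top their neighbor)."""
    n = len(density)
    idx = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and density[j + 1] == density[i]:
            j += 1
        left_ok = i == 0 or density[i - 1] < density[i]
        right_ok = j == n - 1 or density[j + 1] < density[i]
        if left_ok and right_ok:
            idx.append(i)
        i = j + 1
    return np.asarray(idx, dtype=int)


def valley_threshold(fractions, bandwidth: float | str = "silverman",
                     grid_size: int = 512,
                     min_mode_ratio: float = 0.2) -> ValleyResult:
    """Valley-method threshold on a sample of fractions in [0, 1].

    The threshold is the argmin of the reflected Gaussian KDE on the open
    interval between its two highest modes.  A local maximum only counts
    as a mode when its density reaches *min_mode_ratio* of the highest
    mode — small side bumps of an undersmoothed unimodal density are not
    modes.  Raises :class:`NoValleyError` for unimodal densities.
    Deterministic.
    """
    x = np.asarray(pd.Series(fractions).dropna(), dtype=float)
    if len(x) < 4:
        raise DataError(f"valley_threshold needs >= 4 samples, got {len(x)}")
    if np.any((x < 0) | (x > 1)):
        raise DataError("fractions must lie in [0, 1]")
    if bandwidth == "silverman":
        bw = _silverman_bandwidth(x)
    else:
        bw = float(bandwidth)
    if bw <= 0:
        raise NoValleyError(
            "degenerate fraction sample (zero spread): density is a single "
            "spike; supply a manual threshold")
    grid = np.linspace(0.0, 1.0, int(grid_size))
    dens = _reflected_kde(x, bw, grid)
    maxima = _local_maxima(dens)
    if len(maxima):
        maxima = maxima[dens[maxima] >= min_mode_ratio * dens[maxima].max()]
    if len(maxima) < 2:
        raise NoValleyError(
            "fraction density is unimodal; no valley exists — supply a "
            "manual threshold")
    heights = dens[maxima]
    order = np.argsort(heights)[::-1]
    top_height = heights[order[1]]
    # candidates: every maximum at least as high as the 2nd-ranked height
    candidates = maxima[heights >= top_height]
    if len(candidates) > 2:
        # exact ties: prefer the pair with the greatest separation
        best = None
        for a in candidates:
            for b in candidates:
                if b <= a:
                    continue
                sep = grid[b] - grid[a]
                if best is None or sep > best[0]:
                    best = (sep, a, b)
        _, i_lo, i_hi = best
        log.warning("tied density maxima; choosing the most separated pair "
                    "(%0.3f, %0.3f)", grid[i_lo], grid[i_hi])
    else:
        i_lo, i_hi = sorted(candidates[:2])
    if i_hi - i_lo < 2:
        raise NoValleyError("modes are adjacent on the grid; no interior valley")
    interior = slice(i_lo + 1, i_hi)
    k = int(np.argmin(dens[interior])) + i_lo + 1
    return ValleyResult(
        threshold=float(grid[k]),
        mode_locations=(float(grid[i_lo]), float(grid[i_hi])),
        mode_heights=(float(dens[i_lo]), float(dens[i_hi])),
        valley_density=float(dens[k]),
        bandwidth=bw,
        grid=grid,
        density=dens,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_subtypes(fractions: pd.Series, threshold: float,
                      meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Label samples AGCT-2 iff fraction >= threshold (else AGCT-1).

    Returns a subtype table (sample_id, fraction, threshold, subtype); the
    overall and, when *meta* is given, per-condition subtype shares are in
    ``table.attrs["summary"]``.
    """
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError(f"threshold must be in (0, 1), got {threshold}")
    fr = pd.Series(fractions).astype(float)
    table = pd.DataFrame({
        "sample_id": fr.index,
        "fraction": fr.to_numpy(),
        "threshold": threshold,
        "subtype": np.where(fr.to_numpy() >= threshold, AGCT2, AGCT1),
    }).reset_index(drop=True)
    n = len(table)
    n2 = int((table["subtype"] == AGCT2).sum())
    summary: dict = {
        "n_samples": n,
        "n_agct1": n - n2,
        "n_agct2": n2,
        "agct1_share_pct": 100.0 * (n - n2) / n if n else float("nan"),
        "agct2_share_pct": 100.0 * n2 / n if n else float("nan"),
    }
    if meta is not None:
        merged = table.merge(meta[["sample_id", "condition"]], on="sample_id",
                             how="left")
        table["condition"] = merged["condition"]
        by_cond = {}
        for cond, sub in table.groupby("condition"):
            k = int((sub["subtype"] == AGCT2).sum())
            by_cond[cond] = {
                "n": len(sub), "n_agct2": k,
                "agct2_share_pct": 100.0 * k / len(sub),
            }
        summary["by_condition"] = by_cond
    table.attrs["summary"] = summary
    return table
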