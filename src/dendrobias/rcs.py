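"""Size-based Regional Curve Standardization (RCS).

Classical RCS divides each ring by the population-mean ring expected at
the tree's *age*; the size-based variant used here divides each annual
diameter increment by the population-mean increment expected at the
tree's current *diameter*.  Standardized indices are dimensionless with
expectation 1 under the population model, and a regression of log index
on calendar year gives an alternative, whole-trajectory trend estimate
— useful for showing that the demographic bias of clustered recruitment
is not an artifact of measuring growth in a single size class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simulate import GrowthTrajectory
from .trends import TrendEstimate, pct_per_decade_from_log_slope

__all__ = ["RegionalCurve", "build_regional_curve", "standardize_trajectory", "rcs_trend"]


@dataclass
class RegionalCurve:
    """Population-mean diameter increment as a function of diameter.

    ``mean_growth`` holds the raw per-bin means (NaN where the bin is
    empty); :meth:`expected_at` interpolates linearly across empty bins
    and clamps beyond the occupied range.
    """

    bin_edges: np.ndarray  # length n_bins + 1, cm
    mean_growth: np.ndarray  # cm/yr per bin, NaN where empty
    n_per_bin: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def expected_at(self, diameter) -> np.ndarray:
        """Expected increment (cm/yr) at given diameters."""
        d = np.atleast_1d(np.asarray(diameter, dtype=float))
        ok = ~np.isnan(self.mean_growth)
        if not ok.any():
            raise ValueError("regional curve has no occupied bins")
        return np.interp(d, self.bin_centers[ok], self.mean_growth[ok])


def build_regional_curve(
    trajectories: Sequence[GrowthTrajectory], bin_width_cm: float = 2.0
) -> RegionalCurve:
    """Pool every tree-year (diameter, increment) pair into diameter bins.

    The diameter attached to a year's increment is the diameter at the
    START of that year (before the ring is added), so a tree's first
    ring sits in the [0, bin_width) bin.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    if bin_width_cm <= 0:
        raise ValueError("bin_width_cm must be > 0")
    d_start = np.concatenate([t.diameters - t.increments for t in trajectories])
    inc = np.concatenate([t.increments for t in trajectories])
    n_bins = int(np.floor(d_start.max() / bin_width_cm)) + 1
    edges = np.arange(n_bins + 1) * bin_width_cm
    idx = np.minimum((d_start / bin_width_cm).astype(int), n_bins - 1)
    sums = np.bincount(idx, weights=inc, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return RegionalCurve(bin_edges=edges, mean_growth=means, n_per_bin=counts)


def standardize_trajectory(traj: GrowthTrajectory, curve: RegionalCurve) -> pd.DataFrame:
    """Ring-width indices for one tree: observed / expected at its size.

    Returns a DataFrame with columns ``tree_id``, ``year``, ``index``.
    """
    d_start = traj.diameters - traj.increments
    expected = curve.expected_at(d_start)
    idx = traj.increments / expected
    return pd.DataFrame(
        {"tree_id": traj.tree_id, "year": traj.years, "diameter_cm": d_start, "index": idx}
    )


def rcs_trend(
    indexed: pd.DataFrame,
    per_tree_average: bool = False,
    max_diameter_cm: float | None = None,
    cluster_by_tree: bool = True,
) -> TrendEstimate:
    """Trend of the pooled standardized indices over calendar time.

    Regresses ln(index) on calendar year across all tree-years (every
    tree-year weighted equally; with ``per_tree_average`` each tree
    instead contributes one point at its mean year and mean log index).
    ``max_diameter_cm`` restricts the regression to observations taken at
    diameters every tree can traverse (e.g. the sampling threshold):
    beyond it the regional curve is estimated only from the fast growers
    that got there within the record, which distorts indices.  Because a
    tree's years are not independent, standard errors are tree-clustered
    by default.  Returned in %/decade like every other trend here.
    """
    df = indexed
    if max_diameter_cm is not None and "diameter_cm" in df.columns:
        df = df[df["diameter_cm"] <= max_diameter_cm]
    if per_tree_average:
        grouped = df.assign(log_index=np.log(df["index"])).groupby("tree_id")
        df = pd.DataFrame(
            {
                "year": grouped["year"].mean(),
                "index": np.exp(grouped["log_index"].mean()),
            }
        ).reset_index()
    if len(df) < 3:
        raise ValueError("need at least 3 pooled year-index observations")
    y = np.log(df["index"].to_numpy(float))
    x = df["year"].to_numpy(float)
    X = sm.add_constant(x - x.mean())
    if cluster_by_tree and not per_tree_average and "tree_id" in df.columns:
        fit = sm.OLS(y, X).fit(
            cov_type="cluster", cov_kwds={"groups": df["tree_id"].to_numpy()}
        )
    else:
        fit = sm.OLS(y, X).fit()
    b = float(fit.params[1])
    return TrendEstimate(
        slope_pct_per_decade=pct_per_decade_from_log_slope(b),
        slope_log_per_yr=b,
        se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        n_records=len(df),
        method="rcs",
        aic=float(fit.aic),
    )
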