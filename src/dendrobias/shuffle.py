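"""The recruitment-shuffling null: the trend demography alone would produce.

Permuting the recruitment years among the sampled trees of one species
(within one size class) destroys any real calendar-time signal in growth
— each tree keeps its growth rate and its age at the size class, only
its position in time moves — while exactly preserving the number of
recruits per year.  Any trend remaining in the shuffled data is caused
purely by the recruitment-time distribution.  Repeating the permutation
gives a null distribution of slopes against which the apparent
(observed) trend can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .trends import TrendEstimate, pct_per_decade_from_log_slope

__all__ = [
    "ShuffleResult",
    "shuffle_once",
    "estimate_shuffled_trend",
    "compare_apparent_vs_shuffled",
]


@dataclass
class ShuffleResult:
    """Null distribution of %-per-decade slopes under recruitment shuffling.

    ``null_intercept_log``/``null_slope_log`` describe the mean shuffled
    trend line on the log scale, ``ln g = a + b * (year - year_center)``;
    :meth:`predict_growth` evaluates it on the measurement (cm/yr) scale.
    ``t_statistic``/``t_p_value`` are the one-sample two-tailed t-test of
    the per-replicate slopes against zero.
    """

    mean_slope_pct_per_decade: float
    sd_slope_pct: float
    per_rep_slopes: np.ndarray  # %/decade, length n_reps
    n_reps: int
    t_statistic: float
    t_p_value: float
    null_intercept_log: float
    null_slope_log: float
    year_center: float
    n_discarded: int = 0

    def predict_growth(self, years) -> np.ndarray:
        """Growth (cm/yr) predicted by the mean shuffled trend line."""
        years = np.asarray(years, dtype=float)
        return np.exp(self.null_intercept_log + self.null_slope_log * (years - self.year_center))


def shuffle_once(records: pd.DataFrame, rng) -> pd.DataFrame:
    """One permutation of recruitment years among the trees of a species.

    Growth and age-at-class stay glued to their tree; the new calendar
    year at the class follows from the reassigned recruitment year.  The
    multiset of recruitment years is preserved exactly.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = records.copy()
    perm = rng.permutation(len(out))
    out["recruitment_year"] = records["recruitment_year"].to_numpy()[perm]
    out["year_at_class"] = out["recruitment_year"] + out["age_at_class"] - 1
    return out


def _slope_log(years: np.ndarray, log_g: np.ndarray) -> tuple[float, float]:
    """OLS slope and intercept of log growth on (uncentered) year offsets."""
    ym = years.mean()
    x = years - ym
    denom = float(x @ x)
    b = float(x @ (log_g - log_g.mean())) / denom
    a = float(log_g.mean())
    return b, a


def estimate_shuffled_trend(
    records: pd.DataFrame,
    n_reps: int = 500,
    seed=None,
    sampling_year: Optional[int] = None,
) -> ShuffleResult:
    """Monte-Carlo null distribution of size-class trends under shuffling.

    By default a shuffled tree whose new year-at-class lands after the
    census year is kept: re-imposing the survivorship filter would
    reintroduce the demographic selection the null is meant to isolate.
    Pass ``sampling_year`` to re-censor instead (sensitivity analysis).
    Replicates with a degenerate regression (< 3 usable records or no
    year variance) are discarded; more than 10 % discarded is an error.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ages = records["age_at_class"].to_numpy(int)
    recs = records["recruitment_year"].to_numpy(int)
    log_g = np.log(records["growth_cm_yr"].to_numpy(float))
    center = float((recs + ages - 1).mean())

    slopes_log = []
    intercepts = []
    n_discarded = 0
    for _ in range(n_reps):
        perm = rng.permutation(len(recs))
        years = recs[perm] + ages - 1
        lg = log_g
        if sampling_year is not None:
            keep = years <= sampling_year
            years, lg = years[keep], log_g[keep]
        if len(years) < 3 or np.ptp(years) == 0:
            n_discarded += 1
            continue
        x = years - center
        denom = float(((x - x.mean()) ** 2).sum())
        b = float((x - x.mean()) @ (lg - lg.mean())) / denom
        a = float(lg.mean() - b * x.mean())
        slopes_log.append(b)
        intercepts.append(a)
    if n_discarded > 0.10 * n_reps:
        raise RuntimeError(
            f"{n_discarded}/{n_reps} shuffle replicates had degenerate regressions"
        )

    slopes_log = np.asarray(slopes_log)
    slopes_pct = 100.0 * (np.exp(10.0 * slopes_log) - 1.0)
    if np.ptp(slopes_pct) == 0.0:  # all replicates identical: t-test degenerate
        t_stat, t_p = (0.0, 1.0) if slopes_pct[0] == 0.0 else (np.inf, 0.0)
    else:
        t_stat, t_p = stats.ttest_1samp(slopes_pct, 0.0)
    return ShuffleResult(
        mean_slope_pct_per_decade=float(slopes_pct.mean()),
        sd_slope_pct=float(slopes_pct.std(ddof=1)) if len(slopes_pct) > 1 else 0.0,
        per_rep_slopes=slopes_pct,
        n_reps=n_reps,
        t_statistic=float(t_stat),
        t_p_value=float(t_p),
        null_intercept_log=float(np.mean(intercepts)),
        null_slope_log=float(slopes_log.mean()),
        year_center=center,
        n_discarded=n_discarded,
    )


def compare_apparent_vs_shuffled(
    apparent: TrendEstimate, null: ShuffleResult
) -> tuple[float, str]:
    """Signed excess of the apparent trend over the demographic null.

    Returns ``(excess_pct_per_decade, classification)`` where the
    classification is ``above_null`` / ``at_null`` / ``below_null``
    according to whether the apparent slope lies within two null SDs of
    the null mean.  An apparent trend well below the null is the
    signature of an additional negative bias (e.g. predeath mortality);
    one above the null indicates growth genuinely increased.
    """
    excess = apparent.slope_pct_per_decade - null.mean_slope_pct_per_decade
    band = 2.0 * null.sd_slope_pct
    if excess > band:
        cls = "above_null"
    elif excess < -band:
        cls = "below_null"
    else:
        cls = "at_null"
    return excess, cls
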