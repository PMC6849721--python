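"""Growth-trend estimation on size-class records.

Trends are slopes of log growth on the calendar year a tree reached the
size class, reported in percent per decade via the exponential
back-transform

    pct_per_decade = 100 * (exp(10 * slope_log_per_yr) - 1),

the only definition under which "x % per decade" compounds consistently
over time.  Single species use OLS; multi-species aggregation uses a
linear mixed model with species-level random intercept and slope,
optionally with age at the size class as a
second fixed covariate and optionally on species-standardized growth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "TrendEstimate",
    "TrendEstimationError",
    "pct_per_decade_from_log_slope",
    "log_slope_from_pct_per_decade",
    "fit_loglinear_trend",
    "fit_multispecies_trend",
    "trend_since",
]


class TrendEstimationError(ValueError):
    """Raised when a trend cannot be estimated (too few records, no
    variance in year, non-positive growth)."""


def pct_per_decade_from_log_slope(slope_log_per_yr: float) -> float:
    return 100.0 * (math.exp(10.0 * slope_log_per_yr) - 1.0)


def log_slope_from_pct_per_decade(pct: float) -> float:
    return math.log(1.0 + pct / 100.0) / 10.0


@dataclass
class TrendEstimate:
    """A %-per-decade growth trend with its uncertainty.

    ``se`` and the confidence bounds are on the log-per-year scale of the
    underlying regression; ``ci95_pct`` is the back-transformed 95 %
    interval on the %/decade scale.
    """

    slope_pct_per_decade: float
    slope_log_per_yr: float
    se: float
    p_value: float
    n_records: int
    method: str  # ols_single_species | lmm_multispecies | rcs
    aic: Optional[float] = None
    flags: tuple[str, ...] = ()

    @property
    def ci95_pct(self) -> tuple[float, float]:
        lo = self.slope_log_per_yr - 1.96 * self.se
        hi = self.slope_log_per_yr + 1.96 * self.se
        return (pct_per_decade_from_log_slope(lo), pct_per_decade_from_log_slope(hi))


def _validate(records: pd.DataFrame, min_n: int = 3) -> None:
    if len(records) < min_n:
        raise TrendEstimationError(f"need at least {min_n} records, got {len(records)}")
    if (records["growth_cm_yr"] <= 0).any():
        raise TrendEstimationError("all growth values must be > 0 for a log-linear trend")
    if records["year_at_class"].nunique() < 2:
        raise TrendEstimationError("no variance in year_at_class")


def fit_loglinear_trend(records: pd.DataFrame, method: str = "ols_single_species") -> TrendEstimate:
    """OLS of ln(growth) on calendar year at the size class."""
    _validate(records)
    y = np.log(records["growth_cm_yr"].to_numpy(float))
    year = records["year_at_class"].to_numpy(float)
    X = sm.add_constant(year - year.mean())  # centering leaves the slope unchanged
    fit = sm.OLS(y, X).fit()
    b = float(fit.params[1])
    return TrendEstimate(
        slope_pct_per_decade=pct_per_decade_from_log_slope(b),
        slope_log_per_yr=b,
        se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        n_records=len(records),
        method=method,
        aic=float(fit.aic),
    )


def fit_multispecies_trend(
    records: pd.DataFrame,
    include_age: bool = False,
    standardize: bool = False,
) -> TrendEstimate:
    """Aggregated trend across species from a linear mixed model.

    ln(growth) (divided first by the species mean when ``standardize``) is
    regressed on calendar year with a species-level random intercept and
    random year slope; with ``include_age`` the age at which each tree
    reached the class enters as a second fixed covariate, absorbing the
    age-to-calendar-year signal a clustered recruitment history creates.
    Fitted by maximum likelihood so AICs are comparable across fixed-effect
    structures.  Singular or non-converged fits fall back to simpler
    random-effect structures; the fallback is recorded in ``flags``.
    """
    _validate(records)
    n_species = records["species"].nunique()
    if n_species < 2:
        est = fit_loglinear_trend(records, method="lmm_multispecies")
        if include_age:
            est = _ols_with_age(records)
        est.flags = est.flags + ("single_species_ols_fallback",)
        return est
    counts = records.groupby("species").size()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise TrendEstimationError(f"species with fewer than 3 records: {small}")

    df = records.copy()
    g = df["growth_cm_yr"].to_numpy(float)
    if standardize:
        g = g / df.groupby("species")["growth_cm_yr"].transform("mean").to_numpy(float)
    df["log_g"] = np.log(g)
    df["year_c"] = df["year_at_class"] - df["year_at_class"].mean()
    df["age_c"] = df["age_at_class"] - df["age_at_class"].mean()

    fixed = "log_g ~ year_c" + (" + age_c" if include_age else "")
    attempts = [("~year_c", ()), ("~1", ("random_slope_dropped",))]
    last_err: Optional[Exception] = None
    for re_formula, flags in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(fixed, df, groups=df["species"], re_formula=re_formula)
                fit = model.fit(reml=False, method=["lbfgs", "powell"])
                if not fit.converged:
                    raise RuntimeError("mixed model did not converge")
                se = float(fit.bse_fe["year_c"])
                pval = float(fit.pvalues["year_c"])
            if not (np.isfinite(se) and np.isfinite(pval)):
                raise RuntimeError("singular fit: non-finite standard errors")
            b = float(fit.fe_params["year_c"])
            return TrendEstimate(
                slope_pct_per_decade=pct_per_decade_from_log_slope(b),
                slope_log_per_yr=b,
                se=se,
                p_value=pval,
                n_records=len(df),
                method="lmm_multispecies",
                aic=float(fit.aic),
                flags=flags,
            )
        except Exception as err:  # noqa: BLE001 - any fit failure triggers fallback
            last_err = err
            continue
    # final fallback: plain OLS with species dummies absorbed into intercept
    est = _ols_with_age(records) if include_age else fit_loglinear_trend(
        records, method="lmm_multispecies"
    )
    est.flags = est.flags + ("ols_fallback", f"lmm_failed: {last_err}")
    return est


def _ols_with_age(records: pd.DataFrame) -> TrendEstimate:
    y = np.log(records["growth_cm_yr"].to_numpy(float))
    year = records["year_at_class"].to_numpy(float)
    age = records["age_at_class"].to_numpy(float)
    X = sm.add_constant(np.column_stack([year - year.mean(), age - age.mean()]))
    fit = sm.OLS(y, X).fit()
    b = float(fit.params[1])
    return TrendEstimate(
        slope_pct_per_decade=pct_per_decade_from_log_slope(b),
        slope_log_per_yr=b,
        se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        n_records=len(records),
        method="lmm_multispecies",
        aic=float(fit.aic),
    )


def trend_since(records: pd.DataFrame, start_year: int, estimator=fit_loglinear_trend, **kwargs) -> TrendEstimate:
    """The same trend estimator restricted to records dated ``start_year``
    or later (e.g. trends since 1950)."""
    sub = records[records["year_at_class"] >= start_year]
    if len(sub) < 3:
        raise TrendEstimationError(
            f"fewer than 3 records at or after {start_year} ({len(sub)})"
        )
    return estimator(sub, **kwargs)
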