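"""Bias-risk diagnostics for size-class growth data.

A clustered recruitment history betrays itself in two correlations
computed per species and size class:

- age at class vs growth at class (expected negative whenever growth
  differences persist: slow trees arrive old), and
- age at class vs calendar year at class (near zero under continuous
  regeneration, approaching a perfect 1:1 line when every tree recruited
  in the same year).

A species with a significantly *positive* age-calendar-year relation at
both size classes is flagged as at risk of the nonuniform-age bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GrowthTrajectory

__all__ = [
    "SpeciesDiagnostics",
    "RecruitmentSummary",
    "UndefinedCorrelationError",
    "size_class_correlations",
    "recruitment_summary",
    "flag_clustered",
    "diagnostics_table",
]


class UndefinedCorrelationError(ValueError):
    """A correlation was requested on a zero-variance variable."""


@dataclass(frozen=True)
class SpeciesDiagnostics:
    """Per-species bias-risk diagnostics at one size class."""

    species: str
    class_center_cm: float
    age_growth_r: float
    age_growth_p: float
    age_year_r: float
    age_year_p: float
    n_records: int


@dataclass(frozen=True)
class RecruitmentSummary:
    """Histogram and spread of recruitment years for one species."""

    years: np.ndarray  # histogram bin years (integer calendar years)
    counts: np.ndarray
    sd_years: float
    shape_tag: str = "unknown"


def _pearson(x: np.ndarray, y: np.ndarray, what: str) -> tuple[float, float]:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(f"zero variance in {what}")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def size_class_correlations(
    records: pd.DataFrame,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Pearson (r, p) for age-vs-growth and age-vs-calendar-year.

    Requires at least 4 records of a single species and class.
    """
    if len(records) < 4:
        raise ValueError("need at least 4 records")
    age = records["age_at_class"].to_numpy(float)
    growth = records["growth_cm_yr"].to_numpy(float)
    year = records["year_at_class"].to_numpy(float)
    return (
        _pearson(age, growth, "age or growth"),
        _pearson(age, year, "age or year"),
    )


def recruitment_summary(
    trajectories: Sequence[GrowthTrajectory], shape_tag: str = "unknown"
) -> RecruitmentSummary:
    """Integer-year recruitment histogram plus the SD of recruitment years."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    rec = np.array([t.recruitment_year for t in trajectories], dtype=int)
    lo, hi = rec.min(), rec.max()
    years = np.arange(lo, hi + 1)
    counts = np.bincount(rec - lo, minlength=len(years))
    sd = float(rec.std(ddof=0)) if len(rec) > 1 else 0.0
    return RecruitmentSummary(years=years, counts=counts, sd_years=sd, shape_tag=shape_tag)


def flag_clustered(
    diag_canopy: SpeciesDiagnostics,
    diag_understory: SpeciesDiagnostics,
    alpha: float = 0.05,
) -> bool:
    """True iff the age-calendar-year relation is significantly positive
    at BOTH size classes (strict inequality at ``alpha``)."""
    return all(
        d.age_year_r > 0 and d.age_year_p < alpha
        for d in (diag_canopy, diag_understory)
    )


def diagnostics_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-(species, class) diagnostics for a whole record table.

    Species/class combinations with fewer than 4 records or a degenerate
    variable are silently omitted.  Columns mirror the per-species
    diagnostic layout: correlations and p-values for age-growth and
    age-calendar-year.
    """
    rows = []
    for (sp, center), grp in records.groupby(["species", "class_center_cm"]):
        try:
            (agr, agp), (ayr, ayp) = size_class_correlations(grp)
        except (ValueError, UndefinedCorrelationError):
            continue
        rows.append(
            {
                "species": sp,
                "class_center_cm": center,
                "age_growth_r": agr,
                "age_growth_p": agp,
                "age_year_r": ayr,
                "age_year_p": ayp,
                "n_records": len(grp),
            }
        )
    return pd.DataFrame(rows)
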