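"""Reading and writing ring data.

Two on-disk dialects are supported for tree-level series:

- long-format CSV with columns ``species, tree_id, year`` and either
  ``increment_cm`` (annual diameter increment) or ``ring_width_mm``
  (radial ring width, converted to a diameter increment as 2x width);
- the Tucson/RWL decadal text format of dendrochronology archives, in
  either its 0.01 mm (stop marker 999) or 0.001 mm (stop marker -9999)
  unit convention.

All readers return validated :class:`~dendrobias.simulate.GrowthTrajectory`
objects with contiguous years and strictly positive increments.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import GrowthTrajectory

__all__ = [
    "RingDataError",
    "read_ring_table",
    "write_ring_table",
    "read_rwl",
]


class RingDataError(ValueError):
    """Itemized validation failures in a ring-data file."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


def read_ring_table(
    path,
    dialect: str = "increment_cm",
    trees_path=None,
) -> list[GrowthTrajectory]:
    """Read a long-format CSV of per-tree annual series.

    ``dialect='ring_width_mm'`` converts radial mm to diameter cm
    (x2 for diameter, /10 for mm->cm).  ``trees_path`` may point to a
    per-tree table with columns ``tree_id, recruitment_year, death_year``
    used to set death years; otherwise a series simply ends at its last
    ring.  Years must be contiguous per tree, values positive, and
    (species, tree_id, year) unique.
    """
    if dialect not in ("increment_cm", "ring_width_mm"):
        raise ValueError(f"unknown dialect {dialect!r}")
    value_col = dialect
    df = pd.read_csv(path)
    required = {"species", "tree_id", "year", value_col}
    missing = required - set(df.columns)
    if missing:
        raise RingDataError([f"missing columns: {sorted(missing)}"])

    death_years: dict[str, int] = {}
    if trees_path is not None:
        trees = pd.read_csv(trees_path)
        for row in trees.itertuples():
            if pd.notna(getattr(row, "death_year", None)):
                death_years[str(row.tree_id)] = int(row.death_year)

    problems: list[str] = []
    out: list[GrowthTrajectory] = []
    for (species, tree_id), grp in df.groupby(["species", "tree_id"], sort=True):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy(int)
        vals = grp[value_col].to_numpy(float)
        if len(np.unique(years)) != len(years):
            dup = years[pd.Series(years).duplicated().to_numpy()]
            problems.append(f"{species}/{tree_id}: duplicate year(s) {sorted(set(dup))}")
            continue
        gaps = years[np.flatnonzero(np.diff(years) != 1)]
        if len(gaps):
            problems.append(f"{species}/{tree_id}: gap after year {int(gaps[0])}")
            continue
        if np.any(vals <= 0) or np.any(~np.isfinite(vals)):
            bad = years[(vals <= 0) | ~np.isfinite(vals)]
            problems.append(f"{species}/{tree_id}: non-positive value in year {int(bad[0])}")
            continue
        inc = vals if dialect == "increment_cm" else vals * 2.0 / 10.0
        out.append(
            GrowthTrajectory(
                tree_id=str(tree_id),
                recruitment_year=int(years[0]),
                increments=inc,
                death_year=death_years.get(str(tree_id)),
                species=str(species),
            )
        )
    if problems:
        raise RingDataError(problems)
    return out


def write_ring_table(
    trajectories: Sequence[GrowthTrajectory],
    path,
    trees_path=None,
) -> None:
    """Write trajectories as long CSV (+ optional per-tree table)."""
    rows = []
    for t in trajectories:
        for year, inc in zip(t.years, t.increments):
            rows.append((t.species, t.tree_id, int(year), float(inc)))
    pd.DataFrame(rows, columns=["species", "tree_id", "year", "increment_cm"]).to_csv(
        path, index=False, float_format="%.6f"
    )
    if trees_path is not None:
        trows = [
            (t.species, t.tree_id, t.recruitment_year, t.death_year if t.death_year else "")
            for t in trajectories
        ]
        pd.DataFrame(
            trows, columns=["species", "tree_id", "recruitment_year", "death_year"]
        ).to_csv(trees_path, index=False)


def read_rwl(path, units: Optional[float] = None, species: str = "") -> list[GrowthTrajectory]:
    """Read a Tucson/RWL decadal ring-width file.

    Each data line carries a series id, the decade's first year, and up
    to ten ring widths; a stop marker ends the series.  ``units`` is the
    mm-per-count conversion and is auto-detected from the stop marker
    when omitted: 999 -> 0.01 mm, -9999 -> 0.001 mm.  Radial ring widths
    are converted to diameter increments in cm.
    """
    series: dict[str, list[tuple[int, list[int]]]] = {}
    stop_marker: dict[str, int] = {}
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line or line.startswith(("#", "%")):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise RingDataError([f"line {lineno}: malformed decade row {raw!r}"])
        sid = parts[0]
        try:
            year = int(parts[1])
            vals = [int(v) for v in parts[2:]]
        except ValueError as err:
            raise RingDataError([f"line {lineno}: malformed decade row {raw!r} ({err})"]) from err
        series.setdefault(sid, []).append((year, vals))
        for v in vals:
            if v in (999, -9999):
                stop_marker[sid] = v

    out: list[GrowthTrajectory] = []
    for sid, decades in series.items():
        marker = stop_marker.get(sid, 999)
        unit_mm = units if units is not None else (0.01 if marker == 999 else 0.001)
        years: list[int] = []
        widths: list[int] = []
        stopped = False
        for year, vals in sorted(decades):
            for k, v in enumerate(vals):
                if v == marker:
                    stopped = True
                    break
                years.append(year + k)
                widths.append(v)
            if stopped:
                break
        if not years:
            raise RingDataError([f"series {sid}: no data before stop marker"])
        years_arr = np.array(years)
        if np.any(np.diff(years_arr) != 1):
            raise RingDataError([f"series {sid}: non-contiguous years"])
        inc_cm = np.array(widths, dtype=float) * unit_mm * 2.0 / 10.0
        if np.any(inc_cm <= 0):
            raise RingDataError([f"series {sid}: non-positive ring width"])
        out.append(
            GrowthTrajectory(
                tree_id=sid,
                recruitment_year=int(years_arr[0]),
                increments=inc_cm,
                species=species,
            )
        )
    return out
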