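import numpy as np
import pandas as pd
import pytest

from dendrobias import GrowthTrajectory
from dendrobias.sampling import RECORD_COLUMNS


def make_records(species, growth, year, age=None, recruit=None, center=27.0):
    """Assemble a size-class record table from parallel sequences.

    Exactly one of ``age`` / ``recruit`` may be omitted; the other is
    derived from the calendar convention year = recruit + age - 1.
    """
    growth = np.asarray(growth, float)
    year = np.asarray(year, int)
    n = len(growth)
    if age is None:
        recruit = np.asarray(recruit, int)
        age = year - recruit + 1
    elif recruit is None:
        age = np.asarray(age, int)
        recruit = year - age + 1
    return pd.DataFrame(
        {
            "species": species if not isinstance(species, str) else [species] * n,
            "tree_id": [f"t{i:03d}" for i in range(n)],
            "class_center_cm": center,
            "growth_cm_yr": growth,
            "year_at_class": year,
            "age_at_class": np.asarray(age, int),
            "recruitment_year": np.asarray(recruit, int),
        },
        columns=RECORD_COLUMNS,
    )


def constant_tree(rate, recruit, end, tree_id="t0", species="sp"):
    n = end - recruit + 1
    return GrowthTrajectory(
        tree_id=tree_id,
        recruitment_year=recruit,
        increments=np.full(n, float(rate)),
        species=species,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
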