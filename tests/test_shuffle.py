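import itertools

import numpy as np
import pytest

from dendrobias import (
    RecruitmentSpec,
    SamplingDesign,
    StimulationSpec,
    apply_stimulation,
    build_dataset,
    compare_apparent_vs_shuffled,
    estimate_shuffled_trend,
    fit_loglinear_trend,
    shuffle_once,
    simulate_population,
)

from conftest import make_records


def exhaustive_mean_slope_pct(records):
    """Oracle: average %/decade slope over every permutation of the
    recruitment years (independent of the Monte-Carlo implementation)."""
    ages = records["age_at_class"].to_numpy(int)
    log_g = np.log(records["growth_cm_yr"].to_numpy(float))
    recs = records["recruitment_year"].to_numpy(int)
    slopes = []
    for perm in itertools.permutations(recs):
        years = np.asarray(perm) + ages - 1
        if np.ptp(years) == 0:
            continue
        b = np.polyfit(years, log_g, 1)[0]
        slopes.append(100 * (np.exp(10 * b) - 1))
    return float(np.mean(slopes))


class TestShuffleOnce:
    def _records(self):
        return make_records(
            "sp", [1.2, 0.8, 1.0, 0.9], [1950, 1990, 1970, 1965], recruit=[1911, 1911, 1921, 1916]
        )

    def test_preserves_multisets_and_convention(self, rng):
        recs = self._records()
        out = shuffle_once(recs, rng)
        assert sorted(out["recruitment_year"]) == sorted(recs["recruitment_year"])
        np.testing.assert_array_equal(out["growth_cm_yr"], recs["growth_cm_yr"])
        np.testing.assert_array_equal(out["age_at_class"], recs["age_at_class"])
        np.testing.assert_array_equal(
            out["year_at_class"], out["recruitment_year"] + out["age_at_class"] - 1
        )

    def test_single_record_unchanged(self, rng):
        one = self._records().head(1)
        out = shuffle_once(one, rng)
        assert out["year_at_class"].iloc[0] == one["year_at_class"].iloc[0]

    def test_two_record_swap_arithmetic(self):
        # tree A (age 40, recruit 1900), tree B (age 80, recruit 1950):
        # after swapping, A lands in 1989 and B in 1979
        recs = make_records("sp", [1.0, 0.5], [1939, 2029], recruit=[1900, 1950])
        swapped = None
        for seed in range(20):
            out = shuffle_once(recs, np.random.default_rng(seed))
            if out["recruitment_year"].iloc[0] == 1950:
                swapped = out
                break
        assert swapped is not None
        assert list(swapped["year_at_class"]) == [1989, 1979]


class TestShuffledTrend:
    def test_constant_growth_gives_degenerate_null(self):
        recs = make_records("sp", [0.9] * 5, [1940, 1955, 1970, 1985, 2000], age=[40] * 5)
        null = estimate_shuffled_trend(recs, n_reps=50, seed=1)
        assert null.mean_slope_pct_per_decade == pytest.approx(0.0, abs=1e-10)
        assert null.sd_slope_pct == pytest.approx(0.0, abs=1e-10)
        assert null.t_p_value == 1.0

    def test_single_cohort_null_equals_apparent(self):
        # every tree recruited the same year: permutation cannot change the
        # dataset, so the null is the apparent slope with zero spread
        recs = make_records("sp", [1.4, 1.0, 0.7], [1930, 1950, 1970], recruit=[1901] * 3)
        null = estimate_shuffled_trend(recs, n_reps=100, seed=2)
        apparent = fit_loglinear_trend(recs)
        assert null.mean_slope_pct_per_decade == pytest.approx(
            apparent.slope_pct_per_decade, abs=1e-9
        )
        assert null.sd_slope_pct == pytest.approx(0.0, abs=1e-9)
        assert null.mean_slope_pct_per_decade < 0

    def test_monte_carlo_matches_exhaustive_oracle(self):
        recs = make_records(
            "sp",
            [1.3, 1.1, 0.9, 0.75, 0.6],
            [1935, 1955, 1962, 1980, 1995],
            recruit=[1900, 1910, 1905, 1930, 1940],
        )
        exact = exhaustive_mean_slope_pct(recs)
        null = estimate_shuffled_trend(recs, n_reps=10000, seed=3)
        mc_se = null.sd_slope_pct / np.sqrt(null.n_reps)
        assert abs(null.mean_slope_pct_per_decade - exact) < 3 * mc_se

    def test_uniform_recruitment_null_is_near_zero(self):
        from dendrobias import GrowthParams

        pop = simulate_population(
            RecruitmentSpec.uniform(1600, 1920, 300), GrowthParams(), 2010, seed=4
        )
        recs = build_dataset(pop, SamplingDesign(class_centers_cm=(27.0,)))
        null = estimate_shuffled_trend(recs, n_reps=300, seed=5)
        assert abs(null.mean_slope_pct_per_decade) < 0.3

    def test_shuffling_removes_imposed_stimulation(self):
        from dendrobias import GrowthParams

        spec = RecruitmentSpec.unimodal(1900, 20, 150)
        pop = simulate_population(spec, GrowthParams(), 2010, seed=6)
        design = SamplingDesign(class_centers_cm=(27.0,))
        recs = build_dataset(pop, design)
        stim_pop = [apply_stimulation(t, StimulationSpec(1975, 10.0)) for t in pop]
        stim_recs = build_dataset(stim_pop, design)
        null = estimate_shuffled_trend(recs, n_reps=400, seed=7)
        stim_null = estimate_shuffled_trend(stim_recs, n_reps=400, seed=7)
        assert abs(
            stim_null.mean_slope_pct_per_decade - null.mean_slope_pct_per_decade
        ) < 0.5

    def test_t_test_detects_clustered_null(self):
        from dendrobias import GrowthParams

        pop = simulate_population(RecruitmentSpec.unimodal(1900, 20, 200), GrowthParams(), 2010, 8)
        recs = build_dataset(pop, SamplingDesign(class_centers_cm=(27.0,)))
        null = estimate_shuffled_trend(recs, n_reps=500, seed=9)
        assert null.mean_slope_pct_per_decade < 0
        assert null.t_p_value < 0.05
        assert len(null.per_rep_slopes) == 500


class TestApparentVsShuffled:
    def _null(self, mean, sd):
        from dendrobias.shuffle import ShuffleResult

        return ShuffleResult(
            mean_slope_pct_per_decade=mean,
            sd_slope_pct=sd,
            per_rep_slopes=np.array([mean]),
            n_reps=1,
            t_statistic=0.0,
            t_p_value=1.0,
            null_intercept_log=0.0,
            null_slope_log=0.0,
            year_center=1950.0,
        )

    def _apparent(self, pct):
        from dendrobias.trends import TrendEstimate, log_slope_from_pct_per_decade

        return TrendEstimate(pct, log_slope_from_pct_per_decade(pct), 0.0, 1.0, 10, "ols_single_species")

    def test_matching_trends_classified_at_null(self):
        excess, cls = compare_apparent_vs_shuffled(self._apparent(-2.8), self._null(-2.8, 0.4))
        assert excess == pytest.approx(0.0)
        assert cls == "at_null"

    def test_positive_excess_above_null(self):
        excess, cls = compare_apparent_vs_shuffled(self._apparent(2.5), self._null(-0.7, 0.5))
        assert excess == pytest.approx(3.2)
        assert cls == "above_null"

    def test_predeath_signature_below_null(self):
        # strongly more-negative apparent than shuffled, the mortality-bias fingerprint
        excess, cls = compare_apparent_vs_shuffled(self._apparent(-7.24), self._null(-2.41, 0.6))
        assert excess == pytest.approx(-4.83)
        assert cls == "below_null"
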