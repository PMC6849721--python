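import math

import numpy as np
import pytest

from dendrobias import (
    GrowthParams,
    GrowthTrajectory,
    MortalitySpec,
    RecruitmentSpec,
    SpeciesConfig,
    SpeciesPanel,
    StimulationSpec,
    apply_mortality,
    apply_stimulation,
    default_demo_panel,
    draw_recruitment_years,
    generate_species_panel,
    simulate_population,
    simulate_trajectory,
)
from dendrobias.simulate import ConfigurationError


class TestRecruitmentDraws:
    def test_unimodal_moments_match_spec(self):
        spec = RecruitmentSpec.unimodal(1900.0, 20.0, 2000)
        years = draw_recruitment_years(spec, seed=7)
        assert abs(years.mean() - 1900) < 1.0
        assert abs(years.std() - 20) < 1.0

    def test_degenerate_uniform_interval(self):
        years = draw_recruitment_years(RecruitmentSpec.uniform(1800, 1800, 5), seed=0)
        assert (years == 1800).all()

    def test_same_seed_reproduces(self):
        spec = RecruitmentSpec.bimodal(1860, 12, 1930, 12, 0.5, 50)
        a = draw_recruitment_years(spec, seed=3)
        b = draw_recruitment_years(spec, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_exponential_decline_is_reverse_j(self):
        # most trees recruited near the modal (latest) year, few far back
        spec = RecruitmentSpec.exponential(2000, 0.02, 4000)
        years = draw_recruitment_years(spec, seed=1)
        assert (years <= 2000).all()
        assert (years > 1950).mean() > (years <= 1950).mean()
        assert abs(years.mean() - (2000 - 50)) < 3  # Exp mean = 1/decay

    def test_bimodal_has_two_cohorts(self):
        spec = RecruitmentSpec.bimodal(1860, 5, 1940, 5, 0.5, 2000)
        years = draw_recruitment_years(spec, seed=9)
        near_1 = np.abs(years - 1860) < 25
        near_2 = np.abs(years - 1940) < 25
        assert (near_1 | near_2).all()
        assert 0.4 < near_1.mean() < 0.6
        assert ((years > 1885) & (years < 1915)).sum() == 0  # a real gap between cohorts

    @pytest.mark.parametrize(
        "bad",
        [
            dict(shape="gamma", n_trees=5),
            dict(shape="unimodal_normal", n_trees=5, mean=1900, sd=0),
            dict(shape="uniform", n_trees=5, start=1900, end=1800),
            dict(shape="unimodal_normal", n_trees=0, mean=1900, sd=20),
            dict(shape="bimodal_normal", n_trees=5, mean=1900, sd=5, mean2=1950, sd2=5, weight=1.5),
            dict(shape="exponential_decline", n_trees=5, start=1900, decay=0.0),
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            RecruitmentSpec(**bad)


class TestTrajectorySimulation:
    def test_noise_free_is_exact(self):
        p = GrowthParams(mean_log_increment=math.log(0.5), sigma_tree=0.0, sigma_year=0.0)
        traj = simulate_trajectory(p, 1900, 1953, seed=0)
        np.testing.assert_allclose(traj.increments, 0.5)
        assert traj.diameters[-1] == pytest.approx(27.0)
        assert traj.age_at(1953) == 54

    def test_lag1_autocorrelation_from_tree_effect(self):
        # with rho=0 the only serial dependence in log increments is the
        # shared tree effect: corr = sigma_tree^2 / (sigma_tree^2 + sigma_year^2)
        st, sy = 0.3, 0.4
        p = GrowthParams(sigma_tree=st, rho=0.0, sigma_year=sy, max_increment=50.0)
        ss = np.random.SeedSequence(11)
        x0, x1 = [], []
        for child in ss.spawn(400):
            t = simulate_trajectory(p, 1900, 1979, np.random.default_rng(child))
            lg = np.log(t.increments)
            x0.append(lg[:-1])
            x1.append(lg[1:])
        r = np.corrcoef(np.concatenate(x0), np.concatenate(x1))[0, 1]
        expected = st**2 / (st**2 + sy**2)
        assert r == pytest.approx(expected, abs=0.03)

    def test_trees_are_independent(self):
        pop = simulate_population(
            RecruitmentSpec.uniform(1900, 1900, 2), GrowthParams(), 1950, seed=5
        )
        assert not np.allclose(pop[0].increments, pop[1].increments)

    def test_increments_positive_and_capped(self):
        p = GrowthParams(max_increment=1.0, sigma_tree=1.0)
        pop = simulate_population(RecruitmentSpec.unimodal(1900, 20, 50), p, 2000, seed=2)
        for t in pop:
            assert (t.increments > 0).all()
            assert (t.increments <= 1.0).all()
            assert (np.diff(t.diameters) > 0).all()

    def test_deterministic_age_at_diameter_without_noise(self):
        p = GrowthParams(mean_log_increment=math.log(0.45), sigma_tree=0.0, sigma_year=0.0)
        traj = simulate_trajectory(p, 1900, 2010, seed=0)
        age = int(np.argmax(traj.diameters >= 27.0)) + 1
        assert abs(age - 27.0 / 0.45) <= 1  # whole-year rounding


class TestStimulation:
    @pytest.mark.parametrize(
        "pct,year,expected",
        [(5.0, 1975, 1.00), (5.0, 1985, 1.05), (10.0, 2005, 1.30), (0.0, 1999, 1.0)],
    )
    def test_linear_multiplier(self, pct, year, expected):
        stim = StimulationSpec(start_year=1975, pct_per_decade=pct)
        assert stim.multiplier(np.array([year]))[0] == pytest.approx(expected)

    def test_before_start_unchanged_and_zero_is_identity(self):
        traj = simulate_trajectory(GrowthParams(), 1950, 2010, seed=1)
        out = apply_stimulation(traj, StimulationSpec(1975, 5.0))
        pre = traj.years < 1975
        np.testing.assert_array_equal(out.increments[pre], traj.increments[pre])
        ident = apply_stimulation(traj, StimulationSpec(1975, 0.0))
        np.testing.assert_array_equal(ident.increments, traj.increments)

    def test_compound_multiplier_is_loglinear(self):
        stim = StimulationSpec(1900, 2.0, compound=True)
        m = stim.multiplier(np.array([1900, 1910, 2000]))
        np.testing.assert_allclose(m, [1.0, 1.02, 1.02**10])

    def test_negative_multiplier_is_error(self):
        traj = simulate_trajectory(GrowthParams(), 1900, 2010, seed=1)
        with pytest.raises(ValueError):
            apply_stimulation(traj, StimulationSpec(1900, -95.0))


class TestMortality:
    def _population(self, n=150, seed=4):
        return simulate_population(
            RecruitmentSpec.uniform(1900, 1910, n), GrowthParams(), 2000, seed=seed
        )

    def test_zero_hazard_is_identity(self):
        pop = self._population(30)
        out = apply_mortality(pop, MortalitySpec(0.0, 5.0), seed=1)
        for a, b in zip(pop, out):
            assert b.death_year is None
            np.testing.assert_array_equal(a.increments, b.increments)

    def test_constant_hazard_matches_binomial_rate(self):
        h = 0.02
        pop = self._population(400)
        out = apply_mortality(pop, MortalitySpec(h, 0.0), seed=8)
        deaths = sum(1 for t in out if t.death_year is not None)
        at_risk = sum(len(t.increments) for t in out)
        rate = deaths / at_risk
        se = math.sqrt(h * (1 - h) / at_risk)
        assert abs(rate - h) < 4 * se

    def test_growth_dependent_hazard_kills_slow_growers(self):
        pop = self._population(400)
        out = apply_mortality(pop, MortalitySpec(0.02, 10.0), seed=9)
        early = {t.tree_id: t.increments[:5].mean() for t in pop}
        dead = [early[t.tree_id] for t in out if t.death_year is not None]
        alive = [early[t.tree_id] for t in out if t.death_year is None]
        assert len(dead) > 10
        assert np.mean(dead) < np.mean(alive)

    def test_death_truncates_series(self):
        out = apply_mortality(self._population(200), MortalitySpec(0.05, 0.0), seed=3)
        for t in out:
            if t.death_year is not None:
                assert t.last_year == t.death_year
                assert t.death_year >= t.recruitment_year


class TestPanels:
    def test_panel_is_reproducible_byte_identical(self, tmp_path):
        from dendrobias import write_ring_table

        panel = default_demo_panel(seed=13, n_trees=15)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_ring_table(generate_species_panel(panel).all_trajectories(), a)
        write_ring_table(generate_species_panel(panel).all_trajectories(), b)
        assert a.read_bytes() == b.read_bytes()

    def test_duplicate_species_names_rejected(self):
        cfg = SpeciesConfig("x", RecruitmentSpec.unimodal(1900, 20, 5))
        with pytest.raises(ConfigurationError):
            SpeciesPanel(species=[cfg, cfg])

    def test_default_panel_shape_mix(self):
        # 8 clustered (unimodal or two-cohort) vs 4 decline-type species
        panel = default_demo_panel()
        shapes = [s.recruitment.shape for s in panel.species]
        clustered = sum(s in ("unimodal_normal", "bimodal_normal") for s in shapes)
        decline = sum(s in ("uniform", "exponential_decline") for s in shapes)
        assert (clustered, decline) == (8, 4)
        flagged = [s.name for s in panel.species if s.mortality_biased]
        assert len(flagged) == 3

    def test_species_tagged_with_own_config(self):
        panel = default_demo_panel(seed=1, n_trees=5)
        data = generate_species_panel(panel)
        assert set(data.trajectories) == {s.name for s in panel.species}
        for cfg in panel.species:
            for t in data.trajectories[cfg.name]:
                assert t.species == cfg.name
        assert data.shape_tag("Hura crepitans") == "exponential_decline"
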