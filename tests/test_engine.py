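import numpy as np
import pytest

from vsmcabm.engine import SimulationConfig, fold_change, run, seed_population
from vsmcabm.strain import AppliedStrain
from vsmcabm.turnover import TurnoverParams, proliferation_probability


def expected_population_oracle(config: SimulationConfig, n_cohorts: int = 400):
    """Deterministic expected-count recursion for the crowding-free case.

    With zero strain and unconstrained daughter placement every lineage is an
    independent age-structured branching process, so E[N(t)] follows a linear
    recursion over age cohorts: an apoptosis check multiplies every cohort by
    the survival probability, ages advance by one tick, and a proliferation
    check moves mass 2*m*p(age) of each cohort into a fresh age-0 cohort.
    Computed entirely outside the simulator.
    """
    params = config.turnover
    p_death = params.b_apop / 100.0
    n0 = config.initial_cell_count()
    age_max = params.c_prolif
    ages = list((np.arange(n_cohorts) + 0.5) * age_max / n_cohorts)
    mass = [n0 / n_cohorts] * n_cohorts
    for tick in range(1, config.n_ticks + 1):
        if tick % params.apoptosis_interval == 0:
            mass = [m * (1.0 - p_death) for m in mass]
        ages = [a + config.tick_hours for a in ages]
        if tick % params.proliferation_interval == 0:
            born = 0.0
            for i, (a, m) in enumerate(zip(ages, mass)):
                p = proliferation_probability(a, params.c_prolif, params.sigma_prolif)
                divided = m * p
                mass[i] = m - divided
                born += 2.0 * divided
            ages.append(0.0)
            mass.append(born)
    return sum(mass)


class TestSeeding:
    @pytest.mark.parametrize("density,expected", [(5.5e3, 55), (1.33e4, 133)])
    def test_reported_culture_densities(self, density, expected, rng):
        config = SimulationConfig(seeding_density=density)
        pop = seed_population(config, rng)
        assert pop.n == expected

    def test_same_seed_identical_population(self):
        config = SimulationConfig(seeding_density=5.5e3)
        a = seed_population(config, np.random.default_rng(3))
        b = seed_population(config, np.random.default_rng(3))
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.age, b.age)

    def test_no_initial_overlap_and_angles_in_range(self, rng):
        config = SimulationConfig(seeding_density=1.33e4, cell_radius=5.0)
        pop = seed_population(config, rng)
        assert pop.min_neighbor_distance() >= 2 * 5.0
        assert np.all((pop.theta > -np.pi / 2) & (pop.theta <= np.pi / 2))

    def test_impossible_density_reports_achievable(self):
        config = SimulationConfig(seeding_density=1.33e4, cell_radius=60.0)
        with pytest.raises(ValueError, match="achievable density"):
            seed_population(config, np.random.default_rng(0))


class TestRun:
    def test_zero_ticks_returns_seeded_state(self):
        config = SimulationConfig(n_ticks=0)
        result = run(config, seed=5)
        assert result.fold_change(0) == 1.0
        assert len(result.counts) == 1
        assert result.events.empty

    def test_bit_reproducible_under_fixed_seed(self):
        config = SimulationConfig(
            seeding_density=2e4,
            n_ticks=30,
            strain=AppliedStrain.uniaxial_x(0.0, 0.10),
        )
        a = run(config, seed=11)
        b = run(config, seed=11)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert a.events.equals(b.events)
        np.testing.assert_array_equal(a.population.theta, b.population.theta)

    def test_event_log_reconciles_with_counts(self):
        config = SimulationConfig(
            seeding_density=2e4,
            n_ticks=48,
            strain=AppliedStrain.uniaxial_x(0.0, 0.10),
        )
        result = run(config, seed=2)
        births = (result.events["event"] == "birth").sum()
        deaths = (result.events["event"] == "death").sum()
        assert result.counts[-1] == result.counts[0] + births - deaths
        # per-tick reconciliation
        for tick in range(1, config.n_ticks + 1):
            ev = result.events[result.events["tick"] == tick]
            delta = (ev["event"] == "birth").sum() - (ev["event"] == "death").sum()
            assert result.counts[tick] - result.counts[tick - 1] == delta

    def test_no_overlap_after_any_tick(self):
        # a radius large enough that the exclusion constraint actually binds
        config = SimulationConfig(
            seeding_density=2e4, cell_radius=12.96, n_ticks=24, record_every=1
        )
        result = run(config, seed=4)
        for tick, cells in result.snapshots.items():
            if len(cells) < 2:
                continue
            from scipy.spatial import cKDTree

            tree = cKDTree(cells[["x", "y"]].to_numpy())
            d, _ = tree.query(cells[["x", "y"]].to_numpy(), k=2)
            assert d[:, 1].min() >= 2 * 12.96 - 1e-9

    def test_mean_matches_branching_process_oracle(self):
        config = SimulationConfig(seeding_density=1e4, n_ticks=48)
        expected = expected_population_oracle(config)
        counts = np.array([run(config, seed=s).counts[-1] for s in range(50)])
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * max(se, 1e-9)

    def test_fold_change_accessors(self):
        config = SimulationConfig(seeding_density=1e4, n_ticks=10)
        result = run(config, seed=9)
        assert fold_change(result, 0) == 1.0
        assert result.fold_change(10) == result.counts[10] / result.counts[0]
        with pytest.raises(ValueError):
            result.fold_change(11)

    def test_strain_bias_without_reorientation(self):
        """With rotation off, perpendicular cells still out-survive parallel
        ones via selective apoptosis/proliferation alone."""
        from vsmcabm.agents import ReorientationParams
        from vsmcabm.angles import axial_difference

        config = SimulationConfig(
            seeding_density=4e4,
            n_ticks=72,
            strain=AppliedStrain.uniaxial_x(0.0, 0.10),
            reorientation=ReorientationParams(k_rot_c=0.0),
        )
        perp = para = 0
        for seed in range(6):
            theta = run(config, seed=seed).population.theta
            off_axis = np.abs(axial_difference(theta, 0.0))
            perp += int(np.sum(off_axis > np.pi / 3))
            para += int(np.sum(off_axis < np.pi / 6))
        assert perp > para


class TestConfig:
    def test_from_dict_round_trip(self):
        raw = {
            "domain": {"width": 500.0, "height": 400.0, "seeding_density": 1e4},
            "time": {"n_ticks": 12},
            "strain": {"x": [0.0, 0.1], "convention": "half-range"},
            "fiber": {"mean_deg": 90.0, "kappa": 8.0, "density": 1.0},
            "turnover": {"b_apop": 1.5},
            "seed": 3,
        }
        config = SimulationConfig.from_dict(raw)
        assert config.width == 500.0
        assert config.strain.eps_x_max == 0.1
        assert config.fibers.kappa == 8.0
        assert config.fibers.mean_direction == pytest.approx(np.pi / 2)
        assert config.turnover.b_apop == 1.5
        assert config.seed == 3

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(width=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(seeding_density=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(initial_age_rule="bogus")
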