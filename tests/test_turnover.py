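import numpy as np
import pytest

from vsmcabm.agents import Population
from vsmcabm.turnover import (
    TurnoverParams,
    apoptosis_probability,
    apoptosis_sweep,
    doubling_time,
    place_daughter,
    proliferation_probability,
)


class TestApoptosisProbability:
    def test_baseline_without_strain(self):
        params = TurnoverParams()
        assert apoptosis_probability(0.0, params) == pytest.approx(0.0164)

    def test_linear_law_in_percent_units(self):
        params = TurnoverParams(a_apop=1.0, b_apop=1.64)
        # 10% cyclic strain enters the law as 10
        assert apoptosis_probability(0.10, params) == pytest.approx(0.1164)

    def test_immortal_limit(self):
        params = TurnoverParams(a_apop=0.0, b_apop=0.0)
        assert apoptosis_probability(0.5, params) == 0.0

    def test_clamped_to_unit_interval(self):
        params = TurnoverParams(a_apop=1000.0, b_apop=50.0)
        assert apoptosis_probability(0.9, params) == 1.0


class TestDoublingTime:
    def test_unstrained_baseline(self):
        assert doubling_time(0.0, TurnoverParams()) == pytest.approx(71.0)

    def test_quadratic_law_in_fractional_units(self):
        params = TurnoverParams(a_prolif=3500.0, b_prolif=450.0, c_prolif=71.0)
        assert doubling_time(0.1, params) == pytest.approx(3500 * 0.01 + 450 * 0.1 + 71)

    def test_strain_independent_limit(self):
        params = TurnoverParams(a_prolif=0.0, b_prolif=0.0)
        assert doubling_time(0.3, params) == pytest.approx(71.0)

    def test_floored_at_minimum(self):
        params = TurnoverParams(a_prolif=0.0, b_prolif=-1e6, c_prolif=71.0)
        assert doubling_time(0.5, params) == pytest.approx(1.0)


class TestProliferationProbability:
    def test_half_probability_at_doubling_time(self):
        assert proliferation_probability(71.0, 71.0, 9.0) == pytest.approx(0.5)

    def test_vanishes_at_age_zero(self):
        assert proliferation_probability(0.0, 71.0, 9.0) < 1e-14

    def test_saturates_at_one(self):
        assert proliferation_probability(1e6, 71.0, 9.0) == pytest.approx(1.0)

    def test_bounded_and_monotone_in_age(self):
        ages = np.linspace(0.0, 300.0, 200)
        p = proliferation_probability(ages, 71.0, 9.0)
        assert np.all((p >= 0.0) & (p <= 1.0))
        assert np.all(np.diff(p) >= 0.0)


class TestPlaceDaughter:
    def _population(self, coords, radius=1.0):
        pop = Population(radius=radius)
        coords = np.atleast_2d(coords)
        pop.add(coords[:, 0], coords[:, 1], np.zeros(len(coords)),
                np.zeros(len(coords)), np.zeros(len(coords)))
        return pop

    def test_isolated_parent_places_tangent_daughter(self, rng):
        pop = self._population([[50.0, 50.0]])
        spot = place_daughter(pop, 0, 100.0, 100.0, rng)
        assert spot is not None
        assert np.hypot(spot[0] - 50.0, spot[1] - 50.0) == pytest.approx(2.0)

    def test_hexagonally_ringed_parent_has_no_room(self, rng):
        centre = np.array([50.0, 50.0])
        ring = [centre + 2.0 * np.array([np.cos(a), np.sin(a)])
                for a in np.deg2rad(np.arange(0, 360, 60))]
        pop = self._population([centre] + ring)
        assert place_daughter(pop, 0, 100.0, 100.0, rng) is None

    def test_partially_blocked_parent_avoids_neighbors(self, rng):
        centre = np.array([50.0, 50.0])
        ring = [centre + 2.0 * np.array([np.cos(a), np.sin(a)])
                for a in np.deg2rad(np.arange(0, 300, 60))]  # 5 of 6 blocked
        pop = self._population([centre] + ring)
        for _ in range(10):
            spot = place_daughter(pop, 0, 100.0, 100.0, rng)
            assert spot is not None
            d = np.hypot(pop.x - spot[0], pop.y - spot[1])
            assert np.all(d >= 2.0 - 1e-9)

    def test_corner_parent_only_uses_interior_candidates(self, rng):
        pop = self._population([[0.0, 0.0]])
        for _ in range(20):
            spot = place_daughter(pop, 0, 100.0, 100.0, rng)
            assert spot is not None
            assert 0.0 <= spot[0] <= 100.0 and 0.0 <= spot[1] <= 100.0


class TestApoptosisSweep:
    def _population(self, n, rng):
        pop = Population(radius=0.1)
        pop.add(rng.uniform(0, 1000, n), rng.uniform(0, 1000, n),
                np.zeros(n), np.zeros(n), np.zeros(n))
        return pop

    def test_zero_probability_removes_nobody(self, rng):
        pop = self._population(100, rng)
        params = TurnoverParams(a_apop=0.0, b_apop=0.0)
        removed = apoptosis_sweep(pop, np.zeros(100), params, rng)
        assert removed == [] and pop.n == 100

    def test_certain_probability_removes_everybody(self, rng):
        pop = self._population(50, rng)
        params = TurnoverParams(a_apop=0.0, b_apop=100.0)
        removed = apoptosis_sweep(pop, np.zeros(50), params, rng)
        assert len(removed) == 50 and pop.n == 0

    def test_removal_count_matches_binomial_statistics(self, rng):
        n = 10_000
        pop = self._population(n, rng)
        params = TurnoverParams()  # p = 0.0164 at zero strain
        removed = apoptosis_sweep(pop, np.zeros(n), params, rng)
        mean, sd = n * 0.0164, np.sqrt(n * 0.0164 * (1 - 0.0164))
        assert abs(len(removed) - mean) < 3 * sd
        assert pop.n == n - len(removed)
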