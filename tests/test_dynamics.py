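import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rstarsim.dynamics import (
    SystemState,
    deterministic_step,
    monod_term,
    run_trajectory,
    stochastic_step,
)
from rstarsim.parameter_space import RegimeParameters, build_parameter_space


def symmetric_params(mu=0.4, k=4.32, d=0.1, inflow=10.0, quota=1e-6):
    return RegimeParameters(
        mu_a=mu, mu_b=mu, k_a=k, k_b=k, dilution=d, inflow=inflow,
        quota_a=quota, quota_b=quota, regime_label="high_growth", varying="mu",
    )


class TestMonodTerm:
    def test_at_rstar_returns_dilution(self):
        # mu built from R* = 1.44: per-capita rate at R* must balance D
        assert monod_term(0.4, 4.32, 1.44) == pytest.approx(0.1, rel=1e-14)

    def test_zero_resource_gives_zero(self):
        assert monod_term(0.4, 4.32, 0.0) == 0.0

    def test_hand_value(self):
        assert monod_term(0.4, 4.32, 10.0) == pytest.approx(0.4 * 10 / 14.32, rel=1e-14)

    def test_saturates_at_mu(self):
        assert monod_term(0.4, 4.32, 1e12) == pytest.approx(0.4, rel=1e-9)

    def test_negative_resource_rejected(self):
        with pytest.raises(ValueError):
            monod_term(0.4, 4.32, -1.0)


class TestDeterministicStep:
    def test_empty_system_relaxes_resource(self):
        p = symmetric_params()
        s = deterministic_step(SystemState(0.0, 0.0, 4.0), p)
        assert s.n_a == s.n_b == 0.0
        assert s.resource == pytest.approx(4.0 + 0.1 * (10 - 4.0), rel=1e-14)

    def test_single_species_fixed_point_at_rstar(self):
        p = symmetric_params()  # R* = 1.44
        n0 = 1000.0
        s = deterministic_step(SystemState(n0, 0.0, 1.44), p)
        assert s.n_a == pytest.approx(n0, rel=1e-12)

    def test_one_step_frozen_oracle(self, high_growth_points):
        # state (512, 512, 10) at the maximal-inequality point; expected
        # values computed independently with exact rational arithmetic
        p = high_growth_points[0].params
        s = deterministic_step(SystemState(512.0, 512.0, 10.0), p)
        assert s.n_a == pytest.approx(636.97064499746068, rel=1e-12)
        assert s.n_b == pytest.approx(583.32840374113368, rel=1e-12)
        assert s.resource == pytest.approx(9.9997013009512621, rel=1e-12)
        assert s.t == 1

    def test_sub_unit_population_zeroed(self):
        p = symmetric_params()
        s = deterministic_step(SystemState(1.05, 0.0, 0.0), p)
        # no growth at R=0, death leaves 0.945 < 1 -> extinct
        assert s.n_a == 0.0

    def test_symmetry_preserved(self):
        p = symmetric_params()
        state = SystemState(512.0, 512.0, 10.0)
        for _ in range(500):
            state = deterministic_step(state, p)
            assert state.n_a == state.n_b


class TestStochasticStep:
    def test_extinction_absorbing_single_step(self, rng):
        p = symmetric_params()
        s, inc = stochastic_step(SystemState(0, 0, 5.0), p, rng)
        assert s.n_a == s.n_b == 0
        assert inc.realized_births_a == inc.realized_deaths_a == 0

    def test_expectations_match_formulas(self, rng, high_growth_points):
        p = high_growth_points[17].params  # equality point
        _, inc = stochastic_step(SystemState(512, 512, 10.0), p, rng)
        expected_g = 512 * p.mu_a * 10 / (p.k_a + 10)
        assert inc.growth_a == pytest.approx(expected_g, rel=1e-12)
        assert inc.growth_a == pytest.approx(143.02, abs=0.01)
        assert inc.mortality_a == pytest.approx(51.2, rel=1e-12)

    def test_deaths_capped_at_population(self, rng):
        # huge mortality expectation cannot kill more than N individuals
        p = symmetric_params(d=0.3, mu=0.7)
        for _ in range(200):
            s, inc = stochastic_step(SystemState(3, 3, 10.0), p, rng)
            assert inc.realized_deaths_a <= 3
            assert inc.realized_deaths_b <= 3
            assert s.n_a >= 0 and s.n_b >= 0

    def test_uptake_equals_quota_times_births(self, rng):
        p = symmetric_params()
        _, inc = stochastic_step(SystemState(100, 100, 10.0), p, rng)
        assert inc.uptake == pytest.approx(
            p.quota_a * inc.realized_births_a + p.quota_b * inc.realized_births_b
        )

    def test_uptake_capped_by_available_resource(self, rng):
        # enormous quota forces the rationing rule to bind
        p = symmetric_params(quota=0.5)
        for _ in range(300):
            s, inc = stochastic_step(SystemState(50, 50, 3.0), p, rng)
            assert inc.uptake <= 3.0 + 1e-12
            assert s.resource >= 0.0

    def test_rationing_conserves_total_births(self, rng):
        p = symmetric_params(quota=1.0)
        for _ in range(300):
            _, inc = stochastic_step(SystemState(40, 40, 5.0), p, rng)
            assert inc.realized_births_a + inc.realized_births_b <= 5

    def test_non_integer_population_rejected(self, rng):
        p = symmetric_params()
        with pytest.raises(ValueError, match="integer"):
            stochastic_step(SystemState(1.5, 2, 10.0), p, rng)

    def test_single_step_mean_matches_deterministic_increment(self, rng):
        # Monte Carlo oracle: mean stochastic increment vs Eq.-style
        # deterministic expectation, birth and death channels separately
        p = symmetric_params()
        n, r = 64, 10.0
        g = p.mu_a * n * r / (p.k_a + r)
        m = p.dilution * n
        draws = 100_000
        births = np.empty(draws)
        deaths = np.empty(draws)
        for i in range(draws):
            _, inc = stochastic_step(SystemState(n, 0, r), p, rng)
            births[i] = inc.realized_births_a
            deaths[i] = inc.realized_deaths_a
        # P(pois(6.4) > 64) is negligible, so the death cap has no bias
        assert abs(births.mean() - g) <= 3 * math.sqrt(g / draws)
        assert abs(deaths.mean() - m) <= 3 * math.sqrt(m / draws)
        incr = births - deaths
        det_incr = g - m
        assert abs(incr.mean() - det_incr) <= 3 * math.sqrt((g + m) / draws)


class TestRunTrajectory:
    def test_horizon_one_single_step(self, rng):
        p = symmetric_params()
        res = run_trajectory(SystemState(1, 1, 10.0), p, 1, "stochastic", rng)
        assert res.final.t == 1

    def test_deterministic_exclusion_at_max_inequality(self, high_growth_points):
        pt = high_growth_points[0]
        res = run_trajectory(
            SystemState(512.0, 512.0, 10.0), pt.params, 20_000, "deterministic"
        )
        assert res.final.n_b == 0.0  # the higher-R* species is excluded
        assert res.final.n_a > 0.0
        assert res.extinction_time_b is not None
        assert res.extinction_time_b < 20_000
        assert res.extinction_time_a is None
        assert res.final.resource == pytest.approx(1.10, rel=0.01)

    def test_stochastic_dual_extinction_occurs_from_singletons(self, low_growth_points):
        pt = low_growth_points[17]
        dual = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            res = run_trajectory(SystemState(1, 1, 10.0), pt.params, 20_000,
                                 "stochastic", rng)
            if res.final.n_a == 0 and res.final.n_b == 0:
                dual += 1
        assert dual > 0

    def test_resource_bounded_stochastic(self, rng, low_growth_points):
        pt = low_growth_points[0]
        res = run_trajectory(SystemState(8, 8, 10.0), pt.params, 2_000,
                             "stochastic", rng, record=True)
        r = res.trajectory[:, 3]
        assert (r >= 0).all() and (r <= 10.0 + 1e-12).all()

    def test_extinction_absorbing_over_trajectory(self, rng, low_growth_points):
        pt = low_growth_points[17]
        res = run_trajectory(SystemState(2, 2, 10.0), pt.params, 5_000,
                             "stochastic", rng, record=True)
        for col, ext in ((1, res.extinction_time_a), (2, res.extinction_time_b)):
            n = res.trajectory[:, col]
            t = res.trajectory[:, 0]
            if ext is not None:
                assert (n[t >= ext] == 0).all()

    def test_trajectory_recording_stride(self, rng):
        p = symmetric_params()
        res = run_trajectory(SystemState(16, 16, 10.0), p, 100, "stochastic",
                             rng, record=True, record_stride=10)
        assert res.trajectory[0, 0] == 0
        assert res.trajectory[-1, 0] == 100

    def test_requires_rng_for_stochastic(self):
        p = symmetric_params()
        with pytest.raises(ValueError, match="rng"):
            run_trajectory(SystemState(1, 1, 10.0), p, 10, "stochastic")

    def test_final_time_is_horizon_after_early_exit(self, low_growth_points):
        pt = low_growth_points[17]
        # singleton populations at low growth frequently die early
        for seed in range(20):
            rng = np.random.default_rng(seed)
            res = run_trajectory(SystemState(1, 1, 10.0), pt.params, 20_000,
                                 "stochastic", rng)
            assert res.final.t == 20_000

    @given(seed=st.integers(0, 2**32 - 1), n0=st.integers(1, 64))
    @settings(max_examples=25, deadline=None)
    def test_resource_bounds_property(self, seed, n0):
        p = symmetric_params()
        rng = np.random.default_rng(seed)
        res = run_trajectory(SystemState(n0, n0, 10.0), p, 300, "stochastic",
                             rng, record=True)
        r = res.trajectory[:, 3]
        assert (r >= 0).all() and (r <= 10.0 + 1e-12).all()
        pops = res.trajectory[:, 1:3]
        assert (pops >= 0).all()
        assert (pops == pops.astype(int)).all()
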