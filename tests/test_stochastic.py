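"""Discrete stochastic population model: transitions, division, saturation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddadapt import (
    ModelParams,
    PopulationState,
    divide_step,
    markov_step,
    mean_saturation_time,
    run_stochastic,
)
from ddadapt.kinetics import alpha_at, beta_at
from ddadapt.stochastic import mean_trajectory


def _frozen_params(**kw):
    """Parameters with every transition switched off unless overridden."""
    base = dict(gamma1=0.0, gamma_ad=0.0, gamma_r=0.0, delta=0.0,
                alpha_m=0.0, beta_m=0.0)
    base.update(kw)
    return ModelParams(**base)


class TestMarkovStep:
    def test_zero_rates_leave_state_unchanged(self, rng):
        state = PopulationState(step=0, D=100, A=50, R=25)
        out = markov_step(state, _frozen_params(), rng)
        assert (out.D, out.A, out.R, out.dead_cum) == (100, 50, 25, 0)
        assert out.step == 1

    def test_certain_death_of_damaged(self, rng):
        state = PopulationState(step=0, D=100, A=0, R=0)
        out = markov_step(state, _frozen_params(gamma1=1.0), rng)
        assert out.D == 0
        assert out.dead_cum == 100

    def test_per_step_conservation(self, baseline, rng):
        state = PopulationState(step=0, D=baseline.n0, A=0, R=0)
        for _ in range(10):
            new = markov_step(state, baseline, rng)
            # cells are conserved: alive + newly dead balances exactly
            assert new.total + new.dead_cum == state.total + state.dead_cum
            assert new.D <= state.D  # no re-damage
            state = new

    def test_multinomial_expectation_at_first_step(self, baseline):
        """Empirical compartment means match the closed-form multinomial law.

        Oracle: for D0 damaged cells with per-fate probabilities
        (gamma1, beta(1), alpha(1)), the post-step counts are multinomial
        with mean D0*p and variance D0*p*(1-p).
        """
        d0 = 10_000
        a1 = float(alpha_at(1.0, baseline))
        b1 = float(beta_at(1.0, baseline))
        n_rep = 1000
        rng = np.random.default_rng(7)
        remain = np.empty(n_rep)
        repaired = np.empty(n_rep)
        for r in range(n_rep):
            out = markov_step(PopulationState(step=0, D=d0, A=0, R=0), baseline, rng)
            remain[r] = out.D
            repaired[r] = out.R
        p_stay = 1.0 - baseline.gamma1 - a1 - b1
        for emp, p in ((remain, p_stay), (repaired, a1)):
            exp_mean = d0 * p
            se = np.sqrt(d0 * p * (1 - p) / n_rep)
            assert abs(emp.mean() - exp_mean) < 3 * se


class TestDivideStep:
    def test_unconstrained_doubling(self):
        params = ModelParams(n0=20, nmax=100)
        state = PopulationState(step=1, D=0, A=10, R=10)
        out = divide_step(state, params)
        assert (out.A, out.R) == (20, 20)

    def test_proportional_fill_when_space_is_short(self):
        # free = 10 slots, equal demand: each compartment gains 5
        params = ModelParams(n0=20, nmax=30)
        state = PopulationState(step=1, D=0, A=10, R=10)
        out = divide_step(state, params)
        assert (out.A, out.R) == (15, 15)
        assert out.total == params.nmax

    def test_nothing_divides_without_dividers(self):
        params = ModelParams(n0=20, nmax=100)
        state = PopulationState(step=1, D=30, A=0, R=0)
        assert divide_step(state, params) == state

    @given(a=st.integers(0, 500), r=st.integers(0, 500), d=st.integers(0, 200))
    @settings(deadline=None, max_examples=100)
    def test_capacity_bound_and_exact_fill(self, a, r, d):
        nmax = 800
        if a + r + d > nmax:
            return
        params = ModelParams(n0=100, nmax=nmax)
        state = PopulationState(step=1, D=d, A=a, R=r)
        out = divide_step(state, params)
        assert out.total <= nmax
        free = nmax - state.total
        demand = a + r
        if demand > 0 and free > 0:
            assert out.total - state.total == min(demand, free)


class TestRunStochastic:
    def test_certain_repair_doubling_oracle(self):
        """All cells repair at step 1, then R doubles each step.

        Hand iteration with N0=20000, Nmax=100000: R = 20000 after
        transitions at step 1, doubles within the same step's division
        (20000 -> 40000), then 80000, then the last 20000 free slots fill:
        saturation at step 3.
        """
        params = ModelParams(alpha_m=1.0, sigma=1e9, gamma1=0.0, beta_m=0.0)
        for seed in (0, 1, 99):
            res = run_stochastic(params, seed=seed)
            assert res.ts == 3

    def test_no_repair_channel_never_saturates(self):
        params = _frozen_params(gamma1=0.1, beta_m=0.5)  # delta = alpha = 0
        res = run_stochastic(params, seed=5, max_steps=50)
        assert res.ts is None
        assert not res.saturated

    def test_reproducible_from_seed(self, baseline):
        r1 = run_stochastic(baseline, seed=42)
        r2 = run_stochastic(baseline, seed=42)
        assert r1.ts == r2.ts
        assert r1.trajectory == r2.trajectory

    def test_invariants_along_baseline_run(self, baseline):
        res = run_stochastic(baseline, seed=3)
        assert res.saturated
        traj = res.trajectory
        for prev, cur in zip(traj, traj[1:]):
            assert cur.total <= baseline.nmax
            assert cur.D <= prev.D
            assert cur.R >= prev.R  # gamma_r = 0: repaired never die

    def test_saturation_flag_matches_final_state(self, baseline):
        res = run_stochastic(baseline, seed=11)
        assert res.trajectory[-1].R >= baseline.nmax
        assert res.ts == res.trajectory[-1].step


class TestMeanSaturationTime:
    def test_single_replicate_reduces_to_run(self, baseline):
        single = mean_saturation_time(baseline, n_rep=1, base_seed=123)
        assert single.mean == run_stochastic(baseline, seed=123).ts
        assert single.n_saturated == 1

    def test_stderr_shrinks_with_replicates(self, small_pop):
        few = mean_saturation_time(small_pop, n_rep=100, base_seed=0)
        many = mean_saturation_time(small_pop, n_rep=400, base_seed=0)
        assert many.stderr < few.stderr
        # i.i.d. averaging: SE ratio should be ~ sqrt(4), loosely
        assert many.stderr == pytest.approx(few.stderr / 2, rel=0.5)

    def test_all_non_saturating_raises(self):
        params = _frozen_params(gamma1=0.1, beta_m=0.5)
        with pytest.raises(RuntimeError):
            mean_saturation_time(params, n_rep=5, base_seed=0, max_steps=20)

    def test_mean_trajectory_shapes_and_determinism(self, small_pop):
        m1, s1 = mean_trajectory(small_pop, n_rep=50, base_seed=9, n_steps=5)
        m2, _ = mean_trajectory(small_pop, n_rep=50, base_seed=9, n_steps=5)
        assert m1.shape == (3, 6)
        np.testing.assert_array_equal(m1, m2)
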