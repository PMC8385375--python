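"""Fluctuating damage environments: gating, laws, ensembles, expectations."""

import numpy as np
import pytest

from ddadapt import (
    Environment,
    EnvironmentEnsemble,
    GaussianStopLaw,
    ModelParams,
    PointMassLaw,
    UniformStopLaw,
    ExponentialStopLaw,
    build_ensemble,
    expected_over_environment,
    run_ode,
)
from ddadapt.kinetics import alpha_at


class TestGating:
    def test_stop_at_zero_is_the_stable_curve(self, baseline):
        env = Environment(kind="gaussian_stop", stop_time=0.0)
        t = np.linspace(0, 10, 50)
        np.testing.assert_allclose(env.alpha(t, baseline), alpha_at(t, baseline))

    @pytest.mark.parametrize("kind,extra", [
        ("gaussian_stop", {}),
        ("exponential_stop", {}),
        ("uniform_stop_fading", {"fade_rate": 0.3}),
    ])
    def test_no_repair_while_damage_is_ongoing(self, baseline, kind, extra):
        env = Environment(kind=kind, stop_time=2.5, **extra)
        t = np.linspace(0, 2.4999, 40)
        assert np.all(np.asarray(env.alpha(t, baseline)) == 0.0)

    def test_restarted_window_recentres_on_stop_time(self, baseline):
        env = Environment(kind="gaussian_stop", stop_time=2.0)
        # after tau the curve is the original shape on the shifted clock
        assert env.alpha(2.0 + baseline.mu_a, baseline) == pytest.approx(baseline.alpha_m)
        assert env.alpha(5.0, baseline) == pytest.approx(alpha_at(3.0, baseline))

    def test_absolute_window_is_lost_when_stop_is_late(self, baseline):
        env = Environment(kind="gaussian_stop", stop_time=3.0, resume_mode="absolute")
        t = np.linspace(3.0, 10.0, 30)
        # the Gaussian window (centre 1, width 0.5) has essentially passed
        assert np.max(np.asarray(env.alpha(t, baseline))) < 1e-6

    def test_zero_fade_coincides_with_plain_restart(self, baseline):
        tau = 1.8
        fading = Environment(kind="uniform_stop_fading", stop_time=tau, fade_rate=0.0)
        plain = Environment(kind="gaussian_stop", stop_time=tau)
        t = np.linspace(0, 12, 60)
        np.testing.assert_allclose(fading.alpha(t, baseline), plain.alpha(t, baseline))

    def test_gated_run_matches_alpha_zero_before_stop(self, baseline):
        """On [0, tau) the gated dynamics equal a run with repair disabled."""
        tau = 2.0
        env = Environment(kind="gaussian_stop", stop_time=tau)
        gated = run_ode(baseline, env=env, dense_output=True)
        no_repair = run_ode(baseline.replace(alpha_m=0.0), dense_output=True)
        t = np.linspace(0, tau - 1e-9, 50)
        # agreement is limited by the integrator's absolute tolerance
        # (1e-8 * Nmax = 1e-3 cells); allow a small multiple of it
        np.testing.assert_allclose(gated.eval(t), no_repair.eval(t),
                                   rtol=1e-4, atol=2e-2)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            Environment(kind="meteor_strike")
        with pytest.raises(ValueError):
            Environment(kind="gaussian_stop", stop_time=-1.0)
        with pytest.raises(ValueError):
            Environment(kind="gaussian_stop", resume_mode="sideways")


class TestEnsembles:
    def test_point_mass_yields_single_node(self):
        ens = build_ensemble(PointMassLaw(tau=1.3))
        assert len(ens) == 1
        assert ens.weights[0] == 1.0
        assert ens.environments[0].stop_time == 1.3

    def test_gaussian_quadrature_weights_and_mean(self):
        law = GaussianStopLaw(mean=1.7, variance=2.25)
        ens = build_ensemble(law, n_nodes=400)
        assert ens.weights.sum() == pytest.approx(1.0, abs=1e-10)
        # oracle: truncated-normal mean from scipy's closed form
        assert ens.mean_stop_time() == pytest.approx(law.distribution().mean(), abs=1e-3)

    def test_monte_carlo_is_seeded_and_equal_weighted(self):
        law = GaussianStopLaw()
        a = build_ensemble(law, n_nodes=50, method="monte_carlo", seed=3)
        b = build_ensemble(law, n_nodes=50, method="monte_carlo", seed=3)
        np.testing.assert_array_equal(a.stop_times, b.stop_times)
        assert np.all(a.weights == 1 / 50)
        assert np.all(a.stop_times >= 0)

    @pytest.mark.parametrize("law", [
        lambda: GaussianStopLaw(variance=-1.0),
        lambda: ExponentialStopLaw(mean=0.0),
        lambda: UniformStopLaw(low=3.0, high=1.0),
        lambda: UniformStopLaw(fade_rate=-0.5),
    ])
    def test_invalid_laws_rejected(self, law):
        with pytest.raises(ValueError):
            law()

    def test_weight_normalization_enforced(self):
        envs = (Environment(), Environment())
        with pytest.raises(ValueError):
            EnvironmentEnsemble(envs, np.array([0.7, 0.7]))


class TestExpectation:
    def test_single_node_reduces_to_plain_run(self, baseline):
        env = Environment(kind="gaussian_stop", stop_time=1.5)
        ens = EnvironmentEnsemble((env,), np.array([1.0]))
        direct = run_ode(baseline, env=env, t_max=2000.0)
        assert expected_over_environment(baseline, ens) == pytest.approx(direct.ts, abs=1e-9)

    def test_later_stopping_does_not_shorten_saturation(self, baseline):
        """Stochastic dominance: delaying the whole stop-time law by one
        step can only delay the expected saturation time."""
        early = build_ensemble(GaussianStopLaw(mean=1.7), n_nodes=40)
        late = build_ensemble(GaussianStopLaw(mean=2.7), n_nodes=40)
        ts_early = expected_over_environment(baseline, early)
        ts_late = expected_over_environment(baseline, late)
        assert ts_late >= ts_early

    def test_quadrature_agrees_with_monte_carlo(self, baseline):
        """Down-scaled cross-validation of the two estimators."""
        law = GaussianStopLaw()
        quad = expected_over_environment(baseline, build_ensemble(law, n_nodes=100))
        mc_ens = build_ensemble(law, n_nodes=200, method="monte_carlo", seed=11)
        per_node = [
            run_ode(baseline, env=e, t_max=2000.0).ts for e in mc_ens.environments
        ]
        mc_mean = float(np.mean(per_node))
        mc_se = float(np.std(per_node, ddof=1) / np.sqrt(len(per_node)))
        assert abs(quad - mc_mean) < 3 * mc_se

    def test_mass_non_saturating_raises(self, baseline):
        ens = build_ensemble(GaussianStopLaw(), n_nodes=20)
        with pytest.raises(RuntimeError):
            expected_over_environment(baseline, ens, t_max=5.0)

    def test_average_trajectories_on_common_grid(self, baseline):
        """Ensemble-averaged subpopulation time courses stay well defined
        across node saturation times and approach a healthy-full state."""
        from ddadapt import average_trajectories

        ens = build_ensemble(GaussianStopLaw(), n_nodes=10)
        t = np.linspace(0.0, 80.0, 81)
        traj = average_trajectories(baseline, ens, t)
        assert traj.shape == (4, t.size)
        assert np.isfinite(traj).all()
        assert np.all(traj >= -1e-6)
        # by t = 80 every node has saturated: averaged healthy pool ~ Nmax
        healthy_end = traj[2, -1] + traj[3, -1]
        assert healthy_end == pytest.approx(baseline.nmax - 1, rel=1e-3)
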