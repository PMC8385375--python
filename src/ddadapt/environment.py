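"""Fluctuating damage environments and averaging over their distribution.

In the base setting the damage occurs once at time 0 and the repair window
opens immediately ("stable" environment).  In a fluctuating environment the
damage source stays active for a random time ``tau`` (its "stop time"): while
the source is on, no repair is possible, and only once it stops does the
repair window become available.  The adaptation clock is never gated -- cells
have been checkpoint-arrested since the initial damage at t = 0, so
``beta(t)`` always runs on the absolute clock.

Two readings of "repair resumes once the source of damage stops" are
supported, selected by ``resume_mode``:

* ``"restarted"`` (default): the repair window is re-centred on the stop
  time, ``alpha_env(t) = alpha(t - tau)`` for ``t >= tau``.  Repair
  opportunity follows the end of the damage phase, delayed but undiminished.
* ``"absolute"``: the window stays on the absolute clock,
  ``alpha_env(t) = alpha(t)`` for ``t >= tau``.  A source that outlives the
  window destroys most of the repair opportunity, leaving adaptation as the
  only survival route.

The two readings produce qualitatively different population-level optima; see
``docs/methods.md`` for which published phenomenon each one reproduces.

The stop time follows a Gaussian law (truncated at 0), an exponential law, or
a uniform law whose post-stop repair amplitude fades exponentially with the
stop time.  Expectations over the stop-time distribution are computed either
by deterministic trapezoid quadrature on the density (default) or by seeded
Monte-Carlo draws.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from scipy import stats

from .kinetics import ModelParams, alpha_at

__all__ = [
    "Environment",
    "STABLE",
    "GaussianStopLaw",
    "ExponentialStopLaw",
    "UniformStopLaw",
    "PointMassLaw",
    "EnvironmentEnsemble",
    "build_ensemble",
    "expected_over_environment",
    "average_trajectories",
]

logger = logging.getLogger(__name__)

_KINDS = ("stable", "gaussian_stop", "exponential_stop", "uniform_stop_fading")
_RESUME_MODES = ("restarted", "absolute")


@dataclass(frozen=True)
class Environment:
    """One realization of the damage environment.

    ``stop_time`` is the moment the damage source switches off.  Before it,
    the repair probability is zero; after it, the repair curve follows
    ``resume_mode``, scaled by ``exp(-fade_rate * stop_time)`` for the fading
    kind.  ``kind="stable"`` is the identity environment (damage only at 0).
    """

    kind: str = "stable"
    stop_time: float = 0.0
    fade_rate: float = 0.0
    resume_mode: str = "restarted"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown environment kind {self.kind!r}")
        if self.resume_mode not in _RESUME_MODES:
            raise ValueError(f"unknown resume_mode {self.resume_mode!r}")
        if self.stop_time < 0:
            raise ValueError("stop_time must be >= 0")
        if self.fade_rate < 0:
            raise ValueError("fade_rate must be >= 0")

    @property
    def is_stable(self) -> bool:
        return self.kind == "stable" or self.stop_time == 0.0

    def alpha(self, t: Any, params: ModelParams) -> Any:
        """Environment-modulated repair probability at time ``t``."""
        if self.kind == "stable":
            return alpha_at(t, params)
        t_arr = np.asarray(t, dtype=float)
        tau = self.stop_time
        clock = t_arr - tau if self.resume_mode == "restarted" else t_arr
        amp = np.exp(-self.fade_rate * tau)
        out = np.where(t_arr < tau, 0.0, amp * np.asarray(alpha_at(clock, params)))
        return out if out.ndim else float(out)


STABLE = Environment()


class _StopLaw:
    """Common behaviour of stop-time laws (distribution + realization factory)."""

    kind: str
    resume_mode: str
    fade_rate: float = 0.0

    def distribution(self) -> stats.rv_continuous:  # frozen scipy distribution
        raise NotImplementedError

    def make_environment(self, tau: float) -> Environment:
        return Environment(
            kind=self.kind,
            stop_time=float(tau),
            fade_rate=self.fade_rate,
            resume_mode=self.resume_mode,
        )


@dataclass(frozen=True)
class GaussianStopLaw(_StopLaw):
    """Normally distributed stop time, truncated at 0 and renormalized.

    The published fluctuating-environment study uses mean 1.7 and variance
    2.25 (sd 1.5); a stop "before the start" is equivalent to stopping at 0,
    hence the truncation.
    """

    mean: float = 1.7
    variance: float = 2.25
    resume_mode: str = "restarted"
    kind: str = field(default="gaussian_stop", init=False)

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("variance must be > 0")

    def distribution(self) -> stats.rv_continuous:
        sd = float(np.sqrt(self.variance))
        return stats.truncnorm((0.0 - self.mean) / sd, np.inf, loc=self.mean, scale=sd)


@dataclass(frozen=True)
class ExponentialStopLaw(_StopLaw):
    """Exponentially distributed stop time (defaults to the Gaussian law's mean)."""

    mean: float = 1.7
    resume_mode: str = "restarted"
    kind: str = field(default="exponential_stop", init=False)

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("mean must be > 0")

    def distribution(self) -> stats.rv_continuous:
        return stats.expon(scale=self.mean)


@dataclass(frozen=True)
class UniformStopLaw(_StopLaw):
    """Uniform stop time with exponentially fading post-stop repair amplitude."""

    low: float = 0.0
    high: float = 3.4
    fade_rate: float = 0.3
    resume_mode: str = "restarted"
    kind: str = field(default="uniform_stop_fading", init=False)

    def __post_init__(self) -> None:
        if self.low < 0 or self.high <= self.low:
            raise ValueError("require 0 <= low < high")
        if self.fade_rate < 0:
            raise ValueError("fade_rate must be >= 0")

    def distribution(self) -> stats.rv_continuous:
        return stats.uniform(loc=self.low, scale=self.high - self.low)


@dataclass(frozen=True)
class PointMassLaw(_StopLaw):
    """Degenerate law: the source always stops at ``tau`` (mainly for testing)."""

    tau: float = 0.0
    resume_mode: str = "restarted"
    kind: str = field(default="gaussian_stop", init=False)

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclass(frozen=True)
class EnvironmentEnsemble:
    """Weighted collection of environment realizations approximating a law."""

    environments: tuple[Environment, ...]
    weights: np.ndarray
    method: str = "quadrature"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(self.environments) != w.size:
            raise ValueError("environments and weights must have equal length")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.environments)

    @property
    def stop_times(self) -> np.ndarray:
        return np.array([e.stop_time for e in self.environments])

    def mean_stop_time(self) -> float:
        return float(np.dot(self.weights, self.stop_times))


def build_ensemble(
    law: _StopLaw,
    n_nodes: int = 200,
    method: str = "quadrature",
    seed: int | None = None,
) -> EnvironmentEnsemble:
    """Discretize a stop-time law into (environment, weight) nodes.

    Quadrature (default, deterministic): a uniform ``tau`` grid spanning
    [0, q_0.9999 of the law], with trapezoid weights times the density,
    renormalized to sum to 1.  Monte-Carlo: ``n_nodes`` i.i.d. seeded draws
    with equal weights.  A :class:`PointMassLaw` always yields a single node.
    """
    if isinstance(law, PointMassLaw):
        return EnvironmentEnsemble(
            (law.make_environment(law.tau),), np.array([1.0]), method="quadrature"
        )
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    dist = law.distribution()
    if method == "quadrature":
        hi = float(dist.ppf(0.9999))
        taus = np.linspace(0.0, hi, n_nodes)
        dens = dist.pdf(taus)
        # composite trapezoid weights: h/2 at the ends, h inside
        h = taus[1] - taus[0]
        w = dens * h
        w[0] *= 0.5
        w[-1] *= 0.5
        total = w.sum()
        if total <= 0:
            raise ValueError("law has no mass on [0, q_0.9999]")
        w = w / total
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)
        taus = np.maximum(dist.rvs(size=n_nodes, random_state=rng), 0.0)
        w = np.full(n_nodes, 1.0 / n_nodes)
    else:
        raise ValueError(f"unknown ensemble method {method!r}")
    envs = tuple(law.make_environment(tau) for tau in taus)
    return EnvironmentEnsemble(envs, w, method=method)


def expected_over_environment(
    params: ModelParams,
    ensemble: EnvironmentEnsemble,
    functional: Callable[[Any], float] | None = None,
    four_compartment: bool = False,
    t_max: float = 2000.0,
    **ode_kwargs: Any,
) -> float:
    """Weighted expectation of a per-environment scalar over the ensemble.

    Runs the ODE model once per node and applies ``functional`` (default:
    the saturation time) to each result.  Nodes whose run does not saturate
    are excluded and their weight renormalized away; more than 5% excluded
    weight logs a warning, more than 50% is an error.
    """
    from .ode import run_ode  # local import to avoid an import cycle

    if functional is None:
        functional = lambda res: res.ts  # noqa: E731

    values, weights = [], []
    excluded = 0.0
    for env, w in zip(ensemble.environments, ensemble.weights):
        res = run_ode(params, env=env, four_compartment=four_compartment,
                      t_max=t_max, **ode_kwargs)
        if res.ts is None:
            excluded += w
            continue
        values.append(functional(res))
        weights.append(w)
    if excluded > 0.5:
        raise RuntimeError(
            f"{excluded:.1%} of the environment weight did not saturate by t_max={t_max}"
        )
    if excluded > 0.05:
        warnings.warn(
            f"excluded {excluded:.1%} of environment weight (non-saturating nodes)",
            stacklevel=2,
        )
    elif excluded > 0:
        logger.info("excluded %.3g environment weight (non-saturating)", excluded)
    w = np.asarray(weights)
    return float(np.dot(w / w.sum(), np.asarray(values)))


def average_trajectories(
    params: ModelParams,
    ensemble: EnvironmentEnsemble,
    t_grid: Sequence[float],
    four_compartment: bool = True,
    t_max: float = 2000.0,
    hold_after_saturation: bool = True,
    **ode_kwargs: Any,
) -> np.ndarray:
    """Ensemble-averaged compartment trajectories on a common time grid.

    Returns an array of shape ``(n_compartments, len(t_grid))`` holding the
    weighted mean of the per-environment solutions.  After a node saturates,
    its state is held at the saturation value (the run stops there), so the
    average stays defined on the whole grid.
    """
    from .ode import run_ode

    t_grid = np.asarray(t_grid, dtype=float)
    acc = None
    for env, w in zip(ensemble.environments, ensemble.weights):
        res = run_ode(params, env=env, four_compartment=four_compartment,
                      t_max=t_max, dense_output=True, **ode_kwargs)
        traj = res.eval(t_grid, hold_after_saturation=hold_after_saturation)
        acc = w * traj if acc is None else acc + w * traj
    return acc
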