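"""Discrete-time stochastic simulation of the damaged cell population.

Each step is one cell cycle.  Compartment counts evolve by exact multinomial
draws (every cell in a compartment faces the same exclusive per-step fates),
which reproduces the law of the underlying per-cell Markov chain orders of
magnitude faster than an agent-based loop:

* damaged cells: die with gamma1, adapt with beta(n), repair with alpha(n),
  otherwise stay damaged;
* adapted cells: die with gamma_ad, repair with delta, otherwise stay adapted;
* repaired cells: die with gamma_r (zero at baseline);
* at the end of the step, adapted and repaired cells divide within the
  carrying capacity: if there is room, both compartments double; otherwise
  the remaining space is filled proportionally (largest-remainder rounding).

The first transition after the damage uses n = 1, so the repair window
(centred on mu_a = 1) peaks at the first step.  Newly transitioned cells are
in their new compartment at division time.  The saturation time T_S is the
first step with R >= Nmax.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .environment import Environment, STABLE
from .kinetics import ModelParams, beta_at

__all__ = [
    "PopulationState",
    "StochasticRunResult",
    "MeanSaturationResult",
    "markov_step",
    "divide_step",
    "run_stochastic",
    "mean_saturation_time",
]


@dataclass(frozen=True)
class PopulationState:
    """Compartment counts after a given step (all non-negative integers)."""

    step: int
    D: int
    A: int
    R: int
    dead_cum: int = 0

    def __post_init__(self) -> None:
        if min(self.D, self.A, self.R, self.dead_cum) < 0 or self.step < 0:
            raise ValueError(f"negative count in {self}")

    @property
    def total(self) -> int:
        return self.D + self.A + self.R


@dataclass(frozen=True)
class StochasticRunResult:
    trajectory: tuple[PopulationState, ...]
    ts: int | None  # saturation step, or None if not reached
    seed: int

    @property
    def saturated(self) -> bool:
        return self.ts is not None


@dataclass(frozen=True)
class MeanSaturationResult:
    mean: float
    stderr: float
    n_saturated: int
    n_total: int

    @property
    def n_excluded(self) -> int:
        return self.n_total - self.n_saturated


def markov_step(
    state: PopulationState,
    params: ModelParams,
    rng: np.random.Generator,
    env: Environment | None = None,
) -> PopulationState:
    """One round of fate transitions (returns the pre-division state at step n+1).

    A single multinomial per compartment makes the per-step outcomes
    exclusive and conserves cell number exactly.
    """
    if env is None:
        env = STABLE
    n = state.step + 1
    a = float(env.alpha(n, params))
    b = float(beta_at(n, params))
    p_rest = 1.0 - params.gamma1 - b - a
    if p_rest < -1e-12:
        raise ValueError(
            f"gamma1 + alpha({n}) + beta({n}) = {1 - p_rest:.6f} > 1: "
            "invalid per-step multinomial"
        )
    died_d, adapted, repaired, stay_d = rng.multinomial(
        state.D, [params.gamma1, b, a, max(p_rest, 0.0)]
    )
    died_a, repaired_a, stay_a = rng.multinomial(
        state.A, [params.gamma_ad, params.delta, 1.0 - params.gamma_ad - params.delta]
    )
    died_r = rng.binomial(state.R, params.gamma_r) if params.gamma_r > 0 else 0
    return PopulationState(
        step=n,
        D=int(stay_d),
        A=int(stay_a + adapted),
        R=int(state.R - died_r + repaired + repaired_a),
        dead_cum=int(state.dead_cum + died_d + died_a + died_r),
    )


def divide_step(state: PopulationState, params: ModelParams) -> PopulationState:
    """End-of-step division of adapted and repaired cells, capacity-limited.

    Each dividing cell adds one daughter.  With ``free`` slots left and
    ``demand = A + R`` would-be daughters, both compartments double when
    demand fits; otherwise exactly ``free`` daughters are added, split
    proportionally between A and R (largest-remainder integer rounding).
    Division is deterministic given the state.
    """
    free = params.nmax - state.total
    if free < 0:
        raise ValueError("population exceeds carrying capacity before division")
    demand = state.A + state.R
    if demand == 0 or free == 0:
        return state
    if demand <= free:
        add_a, add_r = state.A, state.R
    else:
        add_a = int(np.floor(free * state.A / demand + 0.5))
        add_r = free - add_a
    return PopulationState(
        step=state.step, D=state.D, A=state.A + add_a, R=state.R + add_r,
        dead_cum=state.dead_cum,
    )


def run_stochastic(
    params: ModelParams,
    seed: int,
    max_steps: int = 500,
    env: Environment | None = None,
    keep_trajectory: bool = True,
) -> StochasticRunResult:
    """Simulate one population until R >= Nmax or ``max_steps`` is exhausted.

    Fully reproducible from ``seed``.  Exhausting ``max_steps`` without
    saturation yields a flagged result (``ts is None``), not an exception.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if env is None and params.max_transition_probability() > 1.0 + 1e-12:
        raise ValueError(
            "gamma1 + alpha(t) + beta(t) exceeds 1 at some step: "
            "parameters invalid for the discrete model"
        )
    rng = np.random.default_rng(seed)
    state = PopulationState(step=0, D=params.n0, A=0, R=0)
    trajectory = [state]
    ts: int | None = None
    for _ in range(max_steps):
        state = divide_step(markov_step(state, params, rng, env), params)
        if keep_trajectory:
            trajectory.append(state)
        if state.R >= params.nmax:
            ts = state.step
            break
        if state.total == 0:
            break  # extinct: saturation unreachable
    return StochasticRunResult(
        trajectory=tuple(trajectory) if keep_trajectory else (state,),
        ts=ts, seed=seed,
    )


def mean_saturation_time(
    params: ModelParams,
    n_rep: int,
    base_seed: int,
    max_steps: int = 500,
    env: Environment | None = None,
) -> MeanSaturationResult:
    """Mean and standard error of T_S over ``n_rep`` independent runs.

    Replicate r uses seed ``base_seed + r``.  Non-saturating replicates are
    excluded from the average and reported separately; if every replicate
    fails to saturate this raises.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    times = []
    for r in range(n_rep):
        res = run_stochastic(params, base_seed + r, max_steps=max_steps, env=env,
                             keep_trajectory=False)
        if res.ts is not None:
            times.append(res.ts)
    if not times:
        raise RuntimeError(f"no replicate saturated within {max_steps} steps")
    arr = np.asarray(times, dtype=float)
    se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan")
    return MeanSaturationResult(
        mean=float(arr.mean()), stderr=se,
        n_saturated=arr.size, n_total=n_rep,
    )


def mean_trajectory(
    params: ModelParams,
    n_rep: int,
    base_seed: int,
    n_steps: int,
    env: Environment | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo mean and standard error of (D, A, R) over the first steps.

    Returns ``(mean, stderr)`` with shape ``(3, n_steps + 1)`` including the
    initial state, for comparison against the continuous model.
    """
    acc = np.zeros((n_rep, 3, n_steps + 1))
    for r in range(n_rep):
        res = run_stochastic(params, base_seed + r, max_steps=n_steps, env=env)
        for i, st in enumerate(res.trajectory[: n_steps + 1]):
            acc[r, :, i] = (st.D, st.A, st.R)
        # saturated runs may stop early; hold the last state
        for i in range(len(res.trajectory), n_steps + 1):
            acc[r, :, i] = acc[r, :, len(res.trajectory) - 1]
    mean = acc.mean(axis=0)
    se = acc.std(axis=0, ddof=1) / np.sqrt(n_rep)
    return mean, se
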