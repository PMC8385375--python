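"""Continuous compartment models of cell fate after DNA damage.

Mean-field ODE counterpart of the discrete stochastic model.  With D damaged,
A adapted and R repaired cells, N = D + A + R and crowding factor
(1 - N/Nmax) applied to the growth of the dividing compartments:

    D' = -(gamma1 + beta(t) + alpha_env(t)) D
    A' = beta(t) D - (gamma_ad + delta) A + A (1 - N/Nmax)
    R' = alpha_env(t) D + delta A - gamma_r R + R (1 - N/Nmax)

The lineage-resolved variant splits R into R_d (repaired directly from the
damaged pool, and descendants) and R_a (repaired after adaptation, and
descendants), with R = R_d + R_a an exact refinement:

    R_d' = alpha_env(t) D - gamma_r R_d + R_d (1 - N/Nmax)
    R_a' = delta A       - gamma_r R_a + R_a (1 - N/Nmax)

The saturation time T_S is the first t with Nmax - R(t) < 1 (the environment
is 99.9999% full of healthy cells); it is located by the integrator's event
root-finding on dense output.  Damaged cells have no growth term (they are
checkpoint-arrested) but do occupy carrying-capacity space through N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .environment import Environment, STABLE
from .kinetics import ModelParams, beta_at

__all__ = ["OdeRunResult", "run_ode", "structure_fraction"]

logger = logging.getLogger(__name__)

#: default solver tolerances; atol is scaled to the carrying capacity
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL_PER_NMAX = 1e-8


@dataclass
class OdeRunResult:
    """Dense trajectory of one ODE run plus the saturation time.

    ``ts`` is ``None`` when the population has not saturated by ``t_max``.
    ``state_at_ts`` holds (D, A, R) or (D, A, R_d, R_a) at the saturation
    event.  ``segments`` stores the per-segment ``OdeSolution`` dense outputs
    (fluctuating environments are integrated in two pieces, split at the
    stop time where the repair curve is discontinuous).
    """

    params: ModelParams
    env: Environment
    four_compartment: bool
    ts: float | None
    state_at_ts: np.ndarray | None
    y_final: np.ndarray
    t_final: float
    segments: list = field(default_factory=list, repr=False)
    diagnostics: dict = field(default_factory=dict)

    @property
    def saturated(self) -> bool:
        return self.ts is not None

    @property
    def compartments(self) -> tuple[str, ...]:
        return ("D", "A", "Rd", "Ra") if self.four_compartment else ("D", "A", "R")

    def eval(self, t: Sequence[float], hold_after_saturation: bool = True) -> np.ndarray:
        """Evaluate the dense solution on ``t`` -> array (n_comp, len(t)).

        Requires the run to have been made with ``dense_output=True``.  Times
        past the saturation event return the saturation state when
        ``hold_after_saturation`` (the simulation stops there), else NaN.
        """
        if not self.segments:
            raise ValueError("run_ode(..., dense_output=True) is required for eval()")
        t = np.asarray(t, dtype=float)
        n_comp = 4 if self.four_compartment else 3
        out = np.full((n_comp, t.size), np.nan)
        for sol in self.segments:
            m = (t >= sol.t_min) & (t <= sol.t_max)
            if m.any():
                out[:, m] = sol(t[m])
        past = t > self.t_final
        if past.any():
            if self.saturated and hold_after_saturation:
                out[:, past] = self.state_at_ts[:, None]
            # non-saturating runs keep NaN past t_max
        return out


def _make_rhs(params: ModelParams, env: Environment, four: bool, alpha_off: bool):
    """RHS closure for one integration segment.

    ``alpha_off`` marks the pre-stop segment of a fluctuating environment,
    where no repair is possible.  Within a segment the coefficients are
    smooth, which keeps the adaptive integrator efficient.
    """
    g1, gad, gr, dlt = params.gamma1, params.gamma_ad, params.gamma_r, params.delta
    nmax = float(params.nmax)

    if four:
        def rhs(t: float, y: np.ndarray) -> list[float]:
            D, A, Rd, Ra = np.maximum(y, 0.0)
            n_rel = 1.0 - (D + A + Rd + Ra) / nmax
            a = 0.0 if alpha_off else float(env.alpha(t, params))
            b = beta_at(t, params)
            return [
                -(g1 + b + a) * D,
                b * D - (gad + dlt) * A + A * n_rel,
                a * D - gr * Rd + Rd * n_rel,
                dlt * A - gr * Ra + Ra * n_rel,
            ]
    else:
        def rhs(t: float, y: np.ndarray) -> list[float]:
            D, A, R = np.maximum(y, 0.0)
            n_rel = 1.0 - (D + A + R) / nmax
            a = 0.0 if alpha_off else float(env.alpha(t, params))
            b = beta_at(t, params)
            return [
                -(g1 + b + a) * D,
                b * D - (gad + dlt) * A + A * n_rel,
                a * D + dlt * A - gr * R + R * n_rel,
            ]

    return rhs


def run_ode(
    params: ModelParams,
    env: Environment | None = None,
    t_max: float = 500.0,
    four_compartment: bool = False,
    rtol: float = DEFAULT_RTOL,
    atol: float | None = None,
    method: str = "RK45",
    dense_output: bool = False,
) -> OdeRunResult:
    """Integrate the compartment ODE from (N0, 0, 0[, 0]) up to saturation.

    The saturation event R(t) = Nmax - 1 is located by the solver's root
    finder on dense output (one-sided: R approaches Nmax from below).  A run
    that does not saturate by ``t_max`` is returned flagged, not raised.
    Fluctuating environments are integrated in two segments split at the
    stop time, so the solver never steps across the gating discontinuity.
    """
    if env is None:
        env = STABLE
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    if atol is None:
        atol = DEFAULT_ATOL_PER_NMAX * params.nmax

    nmax = float(params.nmax)
    n_comp = 4 if four_compartment else 3
    y0 = np.zeros(n_comp)
    y0[0] = params.n0

    def saturation(t: float, y: np.ndarray) -> float:
        healthy = y[2] + y[3] if four_compartment else y[2]
        return healthy - (nmax - 1.0)

    saturation.terminal = True
    saturation.direction = 1

    tau = 0.0 if env.is_stable else float(env.stop_time)
    breakpoints = [0.0, tau, t_max] if 0.0 < tau < t_max else [0.0, t_max]

    segments: list = []
    diagnostics: dict[str, Any] = {"nfev": 0, "rtol": rtol, "atol": atol, "method": method}
    ts: float | None = None
    state_at_ts: np.ndarray | None = None
    y = y0
    t_final = t_max
    min_component = 0.0
    for lo, hi in zip(breakpoints[:-1], breakpoints[1:]):
        alpha_off = not env.is_stable and hi <= tau
        rhs = _make_rhs(params, env, four_compartment, alpha_off)
        sol = solve_ivp(
            rhs, (lo, hi), y, method=method, rtol=rtol, atol=atol,
            events=saturation, dense_output=dense_output,
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed on [{lo}, {hi}]: {sol.message}")
        diagnostics["nfev"] += sol.nfev
        if dense_output and sol.sol is not None:
            segments.append(sol.sol)
        min_component = min(min_component, float(sol.y.min()))
        if sol.t_events[0].size:
            ts = float(sol.t_events[0][0])
            state_at_ts = np.asarray(sol.y_events[0][0], dtype=float)
            y = state_at_ts
            t_final = ts
            break
        y = sol.y[:, -1]
        t_final = sol.t[-1]
    if min_component < -atol:
        logger.warning("solver undershoot: min compartment %.3g clipped to 0 in RHS",
                       min_component)
    diagnostics["min_component"] = min_component

    return OdeRunResult(
        params=params, env=env, four_compartment=four_compartment,
        ts=ts, state_at_ts=state_at_ts, y_final=np.asarray(y, dtype=float),
        t_final=t_final, segments=segments, diagnostics=diagnostics,
    )


def structure_fraction(result: OdeRunResult) -> float:
    """Share of healthy cells at saturation descended from adapted cells.

    ``R_a(T_S) / (R_d(T_S) + R_a(T_S))`` -- a proxy for the genetic diversity
    contributed by checkpoint adaptation, since adapted divisions carry
    mutations and rearrangements into the surviving lineage.
    """
    if not result.four_compartment:
        raise ValueError("structure_fraction needs a four-compartment run")
    if not result.saturated:
        raise ValueError("run did not saturate; the final-population structure is undefined")
    _, _, rd, ra = result.state_at_ts
    total = rd + ra
    if total <= 0:
        raise ValueError("no healthy cells at saturation: fraction undefined")
    return float(ra / total)
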