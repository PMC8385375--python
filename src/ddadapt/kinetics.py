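"""Model parameters and the time-varying repair and adaptation curves.

A population of yeast cells receives DNA damage at time 0 and arrests at the
G2/M checkpoint.  Each damaged cell can die, repair, or *adapt* (override the
checkpoint and divide with persistent damage).  Time is measured in cell-cycle
steps (one step is roughly 1.5-2 h of wall time; no conversion to hours is
done anywhere).

Two time-varying probabilities drive the cell-fate kinetics:

* the repair probability ``alpha(t) = alpha_m * exp(-(t - mu_a)^2 / sigma^2)``,
  a Gaussian-shaped window centred on ``mu_a``;
* the adaptation probability ``beta(t) = beta_m / (1 + exp(-p * (t - mu_b)))``,
  a logistic ramp with half-maximum at ``mu_b`` and slope parameter ``p``
  (the slope at the centre is ``p * beta_m / 4``).

Both are used directly as per-step probabilities by the discrete stochastic
model and as continuous-time rates by the ODE model; they are *not*
probability densities and are never renormalised.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from typing import Any, Mapping

import numpy as np
import yaml

__all__ = ["ModelParams", "alpha_at", "beta_at", "baseline_params", "load_params"]

#: grid resolution used when validating sup_t [gamma1 + alpha(t) + beta(t)] <= 1
_VALIDATION_GRID_POINTS = 20001


@dataclass(frozen=True)
class ModelParams:
    """All rate and shape constants of the cell-fate model.

    Defaults are the baseline values used throughout the study:
    an initial pool of 20 000 damaged cells in an environment with carrying
    capacity 100 000, a 10% per-step death hazard while damaged, a 35% hazard
    once adapted (the cost of dividing with damaged chromosomes), no death of
    repaired cells, and a slow (2% per step) adapted-to-repaired channel
    standing in for alternative repair pathways available after division.
    """

    n0: int = 20_000
    nmax: int = 100_000
    gamma1: float = 0.1
    gamma_ad: float = 0.35
    gamma_r: float = 0.0
    delta: float = 0.02
    alpha_m: float = 0.5
    sigma: float = 0.5
    mu_a: float = 1.0
    beta_m: float = 0.5
    p: float = 3.0
    mu_b: float = 3.886

    def __post_init__(self) -> None:
        probs = {
            "gamma1": self.gamma1,
            "gamma_ad": self.gamma_ad,
            "gamma_r": self.gamma_r,
            "delta": self.delta,
            "alpha_m": self.alpha_m,
            "beta_m": self.beta_m,
        }
        bad = [k for k, v in probs.items() if not 0.0 <= v <= 1.0]
        if bad:
            raise ValueError(f"probabilities must lie in [0, 1]: {bad}")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.p <= 0:
            raise ValueError("p must be > 0")
        if self.n0 <= 0 or self.nmax <= 0:
            raise ValueError("population sizes must be positive")
        if self.n0 >= self.nmax:
            raise ValueError("n0 must be smaller than the carrying capacity nmax")
        if self.gamma_ad + self.delta > 1.0:
            raise ValueError("gamma_ad + delta must not exceed 1")

    def max_transition_probability(self) -> float:
        """sup over t of gamma1 + alpha(t) + beta(t), evaluated on a fine grid.

        When this exceeds 1 the parameters are invalid for the *discrete*
        stochastic model (the per-step fates of a damaged cell would not form
        a probability vector); the continuous model treats the curves as
        rates and has no such constraint, so the check is enforced at
        simulation time by the stochastic layer rather than at construction.

        The sum is cheap to bound numerically: alpha decays within a few
        sigma of mu_a and beta saturates at beta_m, so a grid over
        [0, max(mu_a, mu_b) + 10] brackets the maximiser.
        """
        hi = max(self.mu_a + 10.0 * self.sigma, self.mu_b + 10.0)
        t = np.linspace(0.0, hi, _VALIDATION_GRID_POINTS)
        total = self.gamma1 + alpha_at(t, self) + beta_at(t, self)
        return float(np.max(total))

    def replace(self, **changes: Any) -> "ModelParams":
        """Return a copy with the given fields changed (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def alpha_at(t: Any, params: ModelParams) -> Any:
    """Repair probability at time ``t`` (steps since damage).

    Gaussian window ``alpha_m * exp(-(t - mu_a)^2 / sigma^2)``; symmetric
    about ``mu_a`` and peaking there at ``alpha_m``.  Accepts scalars or
    arrays.
    """
    t = np.asarray(t, dtype=float)
    out = params.alpha_m * np.exp(-((t - params.mu_a) ** 2) / params.sigma**2)
    return out if out.ndim else float(out)


def beta_at(t: Any, params: ModelParams) -> Any:
    """Adaptation probability at time ``t``.

    Logistic ramp ``beta_m / (1 + exp(-p (t - mu_b)))``: strictly increasing,
    half-maximal at ``mu_b``, asymptote ``beta_m``.  Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    # clip the exponent to avoid overflow for very early times / steep slopes
    z = np.clip(-params.p * (t - params.mu_b), -700.0, 700.0)
    out = params.beta_m / (1.0 + np.exp(z))
    return out if out.ndim else float(out)


def baseline_params() -> ModelParams:
    """The packaged baseline parameter set (from ``data/baseline.yaml``)."""
    with resources.files("ddadapt").joinpath("data/baseline.yaml").open() as fh:
        return load_params(yaml.safe_load(fh))


def load_params(mapping: Mapping[str, Any] | None) -> ModelParams:
    """Build :class:`ModelParams` from a flat key/value mapping.

    Missing keys take the baseline defaults; unknown keys are rejected.
    """
    mapping = dict(mapping or {})
    known = {f.name for f in dataclasses.fields(ModelParams)}
    unknown = sorted(set(mapping) - known)
    if unknown:
        raise ValueError(f"unknown parameter keys: {unknown}")
    return ModelParams(**mapping)
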