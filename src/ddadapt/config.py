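"""Run configuration: loading, validation, hashing and result serialization.

A run is described by a flat YAML file with up to three blocks::

    params:       # ModelParams fields; missing keys = baseline defaults
      mu_b: 3.886
    environment:  # optional; omitted = stable environment
      kind: gaussian_stop
      mean: 1.7
      variance: 2.25
      resume_mode: restarted
      n_nodes: 200
      method: quadrature
    experiment:   # grids, model choice, replicates, seeds, t_max
      model: ode
      t_max: 500
      replicates: 10000
      base_seed: 0

An empty file is a valid configuration (pure baseline).  Unknown keys are
rejected with a single exhaustive error.  Every result file embeds the
configuration hash so that outputs are traceable to their inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .environment import (
    EnvironmentEnsemble,
    ExponentialStopLaw,
    GaussianStopLaw,
    PointMassLaw,
    UniformStopLaw,
    build_ensemble,
)
from .kinetics import ModelParams, load_params

__all__ = ["RunConfig", "load_config", "config_hash", "write_results"]

_ENV_KEYS = {
    "kind", "mean", "variance", "rate", "low", "high", "fade_rate",
    "resume_mode", "n_nodes", "method", "seed", "stop_time",
}
_EXP_KEYS = {"model", "t_max", "replicates", "base_seed", "mu_b_grid", "p_grid",
             "mu_a_grid", "four_compartment"}

_EXP_DEFAULTS: dict[str, Any] = {
    "model": "ode", "t_max": 500.0, "replicates": 10_000, "base_seed": 0,
    "four_compartment": False,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated, normalized run description."""

    params: ModelParams
    environment: dict[str, Any] | None  # None = stable
    experiment: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "params": self.params.to_dict(),
            "environment": self.environment,
            "experiment": dict(self.experiment),
        }

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())

    def build_environment_ensemble(self) -> EnvironmentEnsemble | None:
        """Instantiate the configured stop-time law as an ensemble (or None)."""
        if self.environment is None:
            return None
        spec = dict(self.environment)
        kind = spec.pop("kind")
        n_nodes = spec.pop("n_nodes", 200)
        method = spec.pop("method", "quadrature")
        seed = spec.pop("seed", None)
        resume = spec.pop("resume_mode", "restarted")
        if kind == "gaussian_stop":
            if "stop_time" in spec:
                law = PointMassLaw(tau=spec.pop("stop_time"), resume_mode=resume)
            else:
                law = GaussianStopLaw(mean=spec.pop("mean", 1.7),
                                      variance=spec.pop("variance", 2.25),
                                      resume_mode=resume)
        elif kind == "exponential_stop":
            mean = spec.pop("mean", None)
            if mean is None and "rate" in spec:
                mean = 1.0 / spec.pop("rate")
            law = ExponentialStopLaw(mean=1.7 if mean is None else mean,
                                     resume_mode=resume)
        elif kind == "uniform_stop_fading":
            law = UniformStopLaw(low=spec.pop("low", 0.0), high=spec.pop("high", 3.4),
                                 fade_rate=spec.pop("fade_rate", 0.3),
                                 resume_mode=resume)
        else:
            raise ValueError(f"unknown environment kind {kind!r}")
        return build_ensemble(law, n_nodes=n_nodes, method=method, seed=seed)


def load_config(path: str | Path | None = None,
                mapping: dict[str, Any] | None = None) -> RunConfig:
    """Load and validate a configuration file (or an in-memory mapping).

    All problems -- unknown blocks, unknown keys, invalid values -- are
    collected and reported in one error.
    """
    if mapping is None:
        raw = yaml.safe_load(Path(path).read_text()) if path is not None else None
    else:
        raw = mapping
    raw = raw or {}
    errors: list[str] = []
    known_blocks = {"params", "environment", "experiment"}
    for key in sorted(set(raw) - known_blocks):
        errors.append(f"unknown top-level block {key!r}")

    params = ModelParams()
    try:
        params = load_params(raw.get("params"))
    except (ValueError, TypeError) as exc:
        errors.append(f"params: {exc}")

    env = raw.get("environment")
    if env is not None:
        if not isinstance(env, dict) or "kind" not in env:
            errors.append("environment: must be a mapping with a 'kind' key")
        else:
            for key in sorted(set(env) - _ENV_KEYS):
                errors.append(f"environment: unknown key {key!r}")
            if env.get("kind") == "stable":
                env = None

    exp = dict(_EXP_DEFAULTS)
    exp_raw = raw.get("experiment") or {}
    if not isinstance(exp_raw, dict):
        errors.append("experiment: must be a mapping")
    else:
        for key in sorted(set(exp_raw) - _EXP_KEYS):
            errors.append(f"experiment: unknown key {key!r}")
        exp.update({k: v for k, v in exp_raw.items() if k in _EXP_KEYS})
        if exp["model"] not in ("ode", "stochastic"):
            errors.append(f"experiment: unknown model {exp['model']!r}")

    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(params=params, environment=env, experiment=exp)


def config_hash(obj: Any) -> str:
    """Stable short hash of a JSON-serializable object (key order independent)."""
    canon = json.dumps(obj, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_results(result: Any, out_dir: str | Path, stem: str,
                  config: RunConfig | None = None) -> dict[str, Path]:
    """Write a sweep/structure/trajectory result as tidy CSV + JSON summary.

    The CSV holds one row per grid point (via the result's ``to_frame``); the
    JSON summary records the argmin/derived quantities, the package version
    and the configuration hash.  Field order is deterministic, so identical
    configurations produce byte-identical files for deterministic models.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    json_path = out_dir / f"{stem}.json"

    if isinstance(result, pd.DataFrame):
        frame = result
    else:
        frame = result.to_frame()
    frame.to_csv(csv_path, index=False)

    summary: dict[str, Any] = {"version": __version__}
    if config is not None:
        summary["config_hash"] = config.hash
    for attr in ("param", "argmin", "ts_at_argmin", "argmin_grid", "interior",
                 "model", "ts_range"):
        if hasattr(result, attr):
            summary[attr] = getattr(result, attr)
    if hasattr(result, "optimal_p"):
        summary["optimal_p_per_mu_b"] = list(map(float, result.optimal_p))
        summary["optimum_kind"] = list(result.optimum_kind)
    if hasattr(result, "fraction"):
        summary["fraction"] = list(map(float, result.fraction))
    if hasattr(result, "meta"):
        summary["meta"] = {k: v for k, v in result.meta.items()}
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=float))
    return {"csv": csv_path, "json": json_path}
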