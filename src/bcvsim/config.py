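"""Run configuration: experiment names, defaults, YAML parsing, validation.

A run is one experiment with a flat key/value configuration.  Defaults fill
in the standard simulation parameters (prior variance 1, inverse temperature
1, 100000 Monte-Carlo trials when sampling); unknown keys and invalid values
are rejected with messages naming the offending key.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["RunConfig", "parse_config", "EXPERIMENT_DEFAULTS"]

# Per-experiment option defaults. Grid endpoints/steps are the package's
# standard sweeps spanning the printed payoffs and parameter values.
EXPERIMENT_DEFAULTS: dict[str, dict[str, Any]] = {
    "binary-scan": dict(R_H=10.0, R_L=6.0, mu_min=-6.0, mu_max=14.0, mu_step=0.5,
                        sigma_R2=[0.1, 1.0, 10.0], sigma_C2=1.0, beta=1.0),
    "trinary-scan": dict(R_H=10.0, R_L=6.0, r3_min=0.0, r3_max=10.0, r3_step=0.5,
                         mu_C=[-2.0, 0.0, 2.0], sigma_R2=0.1, sigma_C2=1.0, beta=1.0),
    "decoy-grid": dict(A=[1.0, 10.0], B=[10.0, 1.0], k_min=1.0, k_max=10.0,
                       k_step=0.5, mu_C=0.0, sigma_R2=0.1, sigma_C2=1.0, beta=1.0),
    "compromise": dict(d_min=0.0, d_max=4.0, d_step=0.5, mu_C=[-2.0, 0.0, 2.0],
                       sigma_R2=[0.1, 1.0, 10.0], sigma_C2=1.0, beta=1.0,
                       include_binary=True),
    "hierarchy": dict(var_HC=1.0, var_HO=1.0, var_LC=1.0, var_LO=1.0, var_R=1.0,
                      HO=0.0, LO=0.0, r_min=-5.0, r_max=5.0, r_step=0.5),
    "scenario": dict(name="magnitude", base=-1.5, prior_var=1.0, obs_var=1.0,
                     reward_var_floor=0.01),
}

_POSITIVE_KEYS = {"sigma_R2", "sigma_C2", "var_HC", "var_HO", "var_LC", "var_LO",
                  "var_R", "prior_var", "obs_var", "reward_var_floor",
                  "mu_step", "r3_step", "k_step", "d_step", "r_step"}
_NONNEGATIVE_KEYS = {"beta"}


@dataclass
class RunConfig:
    """Fully resolved configuration for one experiment run."""

    experiment: str
    seed: int = 0
    n_trials: int = 100_000
    mode: str = "exact"  # "exact" (order enumeration) or "mc"
    out_dir: Path = Path("bcv-results")
    plot: bool = False
    options: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.experiment not in EXPERIMENT_DEFAULTS:
            raise ValueError(
                f"unknown experiment '{self.experiment}'; choose from "
                f"{sorted(EXPERIMENT_DEFAULTS)}")
        if self.mode not in ("exact", "mc"):
            raise ValueError(f"mode must be 'exact' or 'mc', got '{self.mode}'")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        self.seed = int(self.seed)
        self.out_dir = Path(self.out_dir)

    def to_dict(self) -> dict[str, Any]:
        return dict(experiment=self.experiment, seed=self.seed,
                    n_trials=self.n_trials, mode=self.mode,
                    out_dir=str(self.out_dir), plot=self.plot,
                    options=copy.deepcopy(self.options))


def _validate_option(experiment: str, key: str, value: Any) -> Any:
    defaults = EXPERIMENT_DEFAULTS[experiment]
    if key not in defaults:
        raise ValueError(
            f"unknown key '{key}' for experiment '{experiment}'; "
            f"valid keys: {sorted(defaults)}")
    values = value if isinstance(value, (list, tuple)) else [value]
    if key in _POSITIVE_KEYS:
        if any(not isinstance(v, (int, float)) or v <= 0 for v in values):
            raise ValueError(f"key '{key}' must be positive, got {value!r}")
    if key in _NONNEGATIVE_KEYS:
        if any(not isinstance(v, (int, float)) or v < 0 for v in values):
            raise ValueError(f"key '{key}' must be >= 0, got {value!r}")
    return value


def parse_config(path: str | Path | None = None,
                 overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file and/or flat overrides.

    The file (if given) must be a flat mapping containing at least
    ``experiment``; ``overrides`` (e.g. from CLI flags) take precedence.
    Experiment option keys not mentioned are filled from
    :data:`EXPERIMENT_DEFAULTS`.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        raw.update(loaded)
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})

    experiment = raw.pop("experiment", None)
    if experiment is None:
        raise ValueError("config must name an 'experiment'")
    if experiment not in EXPERIMENT_DEFAULTS:
        raise ValueError(
            f"unknown experiment '{experiment}'; choose from "
            f"{sorted(EXPERIMENT_DEFAULTS)}")

    run_keys = {}
    for key in ("seed", "n_trials", "mode", "out_dir", "plot"):
        if key in raw:
            run_keys[key] = raw.pop(key)

    options = dict(EXPERIMENT_DEFAULTS[experiment])
    for key, value in raw.items():
        options[key] = _validate_option(experiment, key, value)

    return RunConfig(experiment=experiment, options=options, **run_keys)
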