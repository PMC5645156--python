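"""Experiment drivers: parameter-grid simulations of choice context effects.

Each driver sweeps a grid of context variables and model parameters over a
fixed choice setup and returns a tidy long-format :class:`pandas.DataFrame`
(one row per grid cell per metric).  Defaults are the setups used throughout
the within-choice simulations: a high/low single-attribute pair
(R_H=10, R_L=6), the two-attribute car pair A=(1,10) vs B=(10,1), and the
compromise triple A=(5-d, 5+d), B=(5+d, 5-d), K=(5,5); prior variance 1 and
inverse temperature 1 unless overridden.

All drivers enumerate presentation orders exactly by default (at most
(3!)^2 = 36 combinations in these setups), so results are deterministic;
pass an :class:`~bcvsim.engine.EngineConfig` to use seeded Monte-Carlo
instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import BCVParams, ChoiceProblem
from .engine import EngineConfig, choice_difference, choice_probs, choice_ratio

__all__ = [
    "GridSpec",
    "RESULT_COLUMNS",
    "run_binary_scan",
    "run_trinary_scan",
    "run_decoy_grid",
    "run_compromise",
    "probe_context_effects",
]

#: Stable column order for every driver's output table.
RESULT_COLUMNS = [
    "experiment", "R_3", "R_p_K", "R_q_K", "d",
    "mu_C", "sigma_R2", "sigma_C2", "beta",
    "metric", "value", "stderr", "method", "n_trials", "seed",
]


@dataclass(frozen=True)
class GridSpec:
    """A named, strictly increasing grid of values for one swept variable."""

    name: str
    values: tuple[float, ...]

    def __post_init__(self):
        values = tuple(float(v) for v in np.asarray(self.values, dtype=float))
        if len(values) == 0:
            raise ValueError(f"grid '{self.name}' must be nonempty")
        if not all(np.isfinite(values)):
            raise ValueError(f"grid '{self.name}' must be finite")
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ValueError(f"grid '{self.name}' must be strictly increasing")
        object.__setattr__(self, "values", values)

    @classmethod
    def linspace(cls, name: str, start: float, stop: float, step: float) -> "GridSpec":
        n = int(round((stop - start) / step)) + 1
        return cls(name, tuple(start + k * step for k in range(n)))


def _default_mu_grid() -> GridSpec:
    return GridSpec.linspace("mu_C", -6.0, 14.0, 0.5)


def _finish(records: list[dict], config: EngineConfig | None) -> pd.DataFrame:
    df = pd.DataFrame.from_records(records)
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["n_trials"] = np.nan if config is None else config.n_trials
    df["seed"] = np.nan if config is None else config.seed
    return df[RESULT_COLUMNS]


def run_binary_scan(R_H: float = 10.0, R_L: float = 6.0,
                    mu_grid: GridSpec | None = None,
                    reward_vars: Sequence[float] = (0.1, 1.0, 10.0),
                    sigma_C2: float = 1.0, beta: float = 1.0,
                    config: EngineConfig | None = None) -> pd.DataFrame:
    """Binary high/low choice: ratio P[R_H]/P[R_L] over a prior-mean grid.

    Reproduces the bell-shaped preference curves over mu_C, one curve per
    reward variance.  Requires ``R_H > R_L``.
    """
    if not R_H > R_L:
        raise ValueError("R_H must exceed R_L")
    mu_grid = mu_grid or _default_mu_grid()
    problem = ChoiceProblem.single_attribute([R_H, R_L], option_labels=("H", "L"))
    records = []
    for sr2 in reward_vars:
        for mu in mu_grid.values:
            dist = choice_probs(problem, BCVParams(mu, sigma_C2, sr2, beta), config)
            records.append(dict(
                experiment="binary-scan", mu_C=mu, sigma_R2=sr2,
                sigma_C2=sigma_C2, beta=beta, metric="choice_ratio",
                value=choice_ratio(dist, 0, 1), stderr=float(dist.stderr[:2].max()),
                method=dist.method))
    return _finish(records, config)


def run_trinary_scan(R_H: float = 10.0, R_L: float = 6.0,
                     r3_grid: GridSpec | None = None,
                     mu_grid: GridSpec | None = None,
                     reward_var: float = 0.1,
                     sigma_C2: float = 1.0, beta: float = 1.0,
                     config: EngineConfig | None = None) -> pd.DataFrame:
    """Two targets plus a third option: ratio P[R_H]/P[R_L] over (R_3, mu_C).

    The signature single-attribute within-choice context effect: at small
    reward variance the ratio follows a U-shaped function of R_3.
    """
    r3_grid = r3_grid or GridSpec.linspace("R_3", 0.0, 10.0, 0.5)
    mu_grid = mu_grid or GridSpec("mu_C", (-2.0, 0.0, 2.0))
    records = []
    for mu in mu_grid.values:
        params = BCVParams(mu, sigma_C2, reward_var, beta)
        for r3 in r3_grid.values:
            problem = ChoiceProblem.single_attribute(
                [R_H, R_L, r3], option_labels=("H", "L", "third"))
            dist = choice_probs(problem, params, config)
            records.append(dict(
                experiment="trinary-scan", R_3=r3, mu_C=mu, sigma_R2=reward_var,
                sigma_C2=sigma_C2, beta=beta, metric="choice_ratio",
                value=choice_ratio(dist, 0, 1), stderr=float(dist.stderr[:2].max()),
                method=dist.method))
    return _finish(records, config)


def _two_attribute_triple(A, B, K) -> ChoiceProblem:
    return ChoiceProblem(
        np.array([[A[0], B[0], K[0]], [A[1], B[1], K[1]]], dtype=float),
        attribute_labels=("price", "quality"), option_labels=("A", "B", "K"))


def run_decoy_grid(A: Sequence[float] = (1.0, 10.0), B: Sequence[float] = (10.0, 1.0),
                   k_p_grid: GridSpec | None = None, k_q_grid: GridSpec | None = None,
                   mu_C: float = 0.0, reward_var: float = 0.1,
                   sigma_C2: float = 1.0, beta: float = 1.0,
                   config: EngineConfig | None = None) -> pd.DataFrame:
    """Two-attribute targets plus a decoy K swept over an attribute grid.

    Reports the choice-probability difference P[A] - P[B] as a function of
    K's price and quality rewards.  A and B are (price, quality) pairs.
    """
    if len(A) != 2 or len(B) != 2:
        raise ValueError("decoy grid requires exactly two attributes")
    k_p_grid = k_p_grid or GridSpec.linspace("R_p_K", 1.0, 10.0, 0.5)
    k_q_grid = k_q_grid or GridSpec.linspace("R_q_K", 1.0, 10.0, 0.5)
    params = BCVParams(mu_C, sigma_C2, reward_var, beta)
    records = []
    for kp in k_p_grid.values:
        for kq in k_q_grid.values:
            dist = choice_probs(_two_attribute_triple(A, B, (kp, kq)), params, config)
            records.append(dict(
                experiment="decoy-grid", R_p_K=kp, R_q_K=kq, mu_C=mu_C,
                sigma_R2=reward_var, sigma_C2=sigma_C2, beta=beta,
                metric="choice_difference", value=choice_difference(dist, 0, 1),
                stderr=float(dist.stderr[:2].max()), method=dist.method))
    return _finish(records, config)


def run_compromise(d_grid: GridSpec | None = None,
                   reward_vars: Sequence[float] = (0.1, 1.0, 10.0),
                   mu_values: Sequence[float] = (-2.0, 0.0, 2.0),
                   include_binary: bool = True,
                   sigma_C2: float = 1.0, beta: float = 1.0,
                   config: EngineConfig | None = None) -> pd.DataFrame:
    """Compromise setup: intermediate option K vs extreme options A and B.

    A=(5-d, 5+d) and B=(5+d, 5-d) mirror each other across attributes;
    K=(5,5) is intermediate on both.  Reports P[K|A,K] - P[A|A,K]
    (``binary_difference``, a control that is zero by symmetry) and
    P[K|A,B,K] - P[A|A,B,K] (``trinary_difference``, the compromise effect)
    over the proximity grid d.
    """
    d_grid = d_grid or GridSpec.linspace("d", 0.0, 4.0, 0.5)
    if any(d < 0 or d > 4 for d in d_grid.values):
        raise ValueError("proximity values d must lie in [0, 4]")
    records = []
    for sr2 in reward_vars:
        for mu in mu_values:
            params = BCVParams(mu, sigma_C2, sr2, beta)
            for d in d_grid.values:
                A, B, K = (5 - d, 5 + d), (5 + d, 5 - d), (5.0, 5.0)
                common = dict(experiment="compromise", d=d, mu_C=mu,
                              sigma_R2=sr2, sigma_C2=sigma_C2, beta=beta)
                if include_binary:
                    binary = ChoiceProblem(
                        np.array([[A[0], K[0]], [A[1], K[1]]]),
                        attribute_labels=("price", "quality"),
                        option_labels=("A", "K"))
                    dist = choice_probs(binary, params, config)
                    records.append(dict(common, metric="binary_difference",
                                        value=choice_difference(dist, 1, 0),
                                        stderr=float(dist.stderr.max()),
                                        method=dist.method))
                dist = choice_probs(_two_attribute_triple(A, B, K), params, config)
                records.append(dict(common, metric="trinary_difference",
                                    value=choice_difference(dist, 2, 0),
                                    stderr=float(dist.stderr.max()),
                                    method=dist.method))
    return _finish(records, config)


# Probe points at which the similarity / attraction context effects are read
# out from the decoy setup: K similar to one target, and a dominated decoy
# near one target, plus their attribute-swap mirrors.
PROBE_POINTS = {
    "similarity_near_B": (9.0, 2.0),
    "similarity_near_A": (2.0, 9.0),
    "attraction_decoy_A": (1.0, 5.0),
    "attraction_decoy_B": (5.0, 1.0),
}


def probe_context_effects(mu_C: float = 0.0, reward_var: float = 0.1,
                          sigma_C2: float = 1.0, beta: float = 1.0,
                          config: EngineConfig | None = None) -> dict[str, float]:
    """Signed choice-probability difference P[A]-P[B] at the four probe decoys.

    Returns one value per probe in :data:`PROBE_POINTS`.  By the
    attribute-swap symmetry of the setup the mirrored probes have values of
    equal magnitude and opposite sign (exactly, under enumeration).
    """
    params = BCVParams(mu_C, sigma_C2, reward_var, beta)
    out = {}
    for name, (kp, kq) in PROBE_POINTS.items():
        dist = choice_probs(_two_attribute_triple((1.0, 10.0), (10.0, 1.0), (kp, kq)),
                            params, config)
        out[name] = choice_difference(dist, 0, 1)
    return out
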