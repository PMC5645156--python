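"""Choice-probability engine: exact order enumeration and Monte-Carlo averaging.

Presentation orders are the only source of randomness in a BCV trial, so
choice probabilities for a problem are an average of softmax distributions
over per-attribute orders.  For small sets ((N!)^I order combinations below
``enumeration_limit``) the average is computed exactly by enumeration, which
makes the in-text reproductions deterministic; otherwise orders are sampled.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .core import BCVParams, ChoiceDistribution, ChoiceProblem

__all__ = [
    "EngineConfig",
    "exact_choice_probs",
    "mc_choice_probs",
    "choice_probs",
    "choice_ratio",
    "choice_difference",
]


@dataclass(frozen=True)
class EngineConfig:
    """Monte-Carlo / enumeration settings.

    ``mc_mode`` selects between averaging softmax probabilities over sampled
    orders (``probability_average``, lower variance) and tallying one sampled
    choice per trial (``sampled_choice``); both are unbiased for the same
    quantity.
    """

    n_trials: int = 100_000
    seed: int = 0
    mc_mode: str = "probability_average"
    enumeration_limit: int = 10_000

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.mc_mode not in ("probability_average", "sampled_choice"):
            raise ValueError("mc_mode must be 'probability_average' or 'sampled_choice'")
        if self.enumeration_limit < 1:
            raise ValueError("enumeration_limit must be >= 1")


def _batch_option_values(problem: ChoiceProblem, params: BCVParams,
                         orders: np.ndarray) -> np.ndarray:
    """Option incentive values for a batch of presentation orders.

    ``orders`` has shape (T, I, N): T order sets, one permutation per
    attribute.  Returns a (T, N) matrix of summed option values.  The
    posterior variance after t updates does not depend on which rewards were
    seen, so gains are shared across the batch and only the posterior mean is
    tracked per order set.
    """
    T = orders.shape[0]
    n_attr, n_opt = problem.n_attributes, problem.n_options
    mu0, var_c, var_r = params.per_attribute(n_attr)

    values = np.zeros((T, n_opt))
    rows = np.arange(T)
    for i in range(n_attr):
        perm = orders[:, i, :]                  # (T, N)
        rewards = problem.rewards[i][perm]      # (T, N) rewards in presentation order
        mean = np.full(T, mu0[i])
        var = var_c[i]
        for t in range(n_opt):
            g = var / (var + var_r[i])
            v = g * (rewards[:, t] - mean)
            mean += v
            var -= g * var
            values[rows, perm[:, t]] += v
    return values


def _softmax_rows(values: np.ndarray, beta: float) -> np.ndarray:
    z = beta * values
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def n_order_combinations(problem: ChoiceProblem) -> int:
    """Number of distinct per-attribute order combinations, (N!)^I."""
    return math.factorial(problem.n_options) ** problem.n_attributes


def exact_choice_probs(problem: ChoiceProblem, params: BCVParams,
                       enumeration_limit: int = 10_000) -> ChoiceDistribution:
    """Choice probabilities by exact enumeration of all order combinations.

    Averages the softmax distribution over all (N!)^I equally likely
    combinations of per-attribute presentation orders.  Raises if the
    combination count exceeds ``enumeration_limit``.
    """
    n_comb = n_order_combinations(problem)
    if n_comb > enumeration_limit:
        raise ValueError(
            f"{n_comb} order combinations exceed enumeration_limit="
            f"{enumeration_limit}; use mc_choice_probs instead")
    perms = list(itertools.permutations(range(problem.n_options)))
    combos = np.array(list(itertools.product(perms, repeat=problem.n_attributes)),
                      dtype=np.intp)  # (n_comb, I, N)
    values = _batch_option_values(problem, params, combos)
    probs = _softmax_rows(values, params.inverse_temperature).mean(axis=0)
    return ChoiceDistribution(probs=probs, stderr=np.zeros_like(probs), method="exact")


def mc_choice_probs(problem: ChoiceProblem, params: BCVParams,
                    config: EngineConfig = EngineConfig()) -> ChoiceDistribution:
    """Choice probabilities by Monte-Carlo over random presentation orders.

    Each trial draws an independent uniform permutation per attribute.
    Identical seeds give bitwise-identical output.
    """
    rng = np.random.default_rng(config.seed)
    T, n_attr, n_opt = config.n_trials, problem.n_attributes, problem.n_options
    orders = np.tile(np.arange(n_opt, dtype=np.intp), (T, n_attr, 1))
    orders = rng.permuted(orders, axis=2)
    values = _batch_option_values(problem, params, orders)
    trial_probs = _softmax_rows(values, params.inverse_temperature)

    if config.mc_mode == "probability_average":
        probs = trial_probs.mean(axis=0)
        if T > 1:
            stderr = trial_probs.std(axis=0, ddof=1) / np.sqrt(T)
        else:
            stderr = np.zeros(n_opt)
    else:  # sampled_choice
        cum = np.cumsum(trial_probs, axis=1)
        u = rng.random(T)
        choices = np.minimum((u[:, None] > cum).sum(axis=1), n_opt - 1)
        counts = np.bincount(choices, minlength=n_opt)
        probs = counts / T
        stderr = np.sqrt(probs * (1.0 - probs) / T)
    # renormalise away accumulated rounding so downstream invariants hold
    probs = probs / probs.sum()
    return ChoiceDistribution(probs=probs, stderr=stderr, method="monte_carlo")


def choice_probs(problem: ChoiceProblem, params: BCVParams,
                 config: EngineConfig | None = None) -> ChoiceDistribution:
    """Exact probabilities when feasible, otherwise seeded Monte-Carlo.

    With ``config=None`` enumeration is mandatory (errors if infeasible);
    with a config, enumeration is used when the combination count is within
    ``config.enumeration_limit`` and MC otherwise.
    """
    if config is None:
        return exact_choice_probs(problem, params)
    if n_order_combinations(problem) <= config.enumeration_limit:
        return exact_choice_probs(problem, params, config.enumeration_limit)
    return mc_choice_probs(problem, params, config)


def choice_ratio(dist: ChoiceDistribution, a: int, b: int) -> float:
    """Ratio P(a)/P(b) of two options' choice probabilities."""
    pa, pb = float(dist.probs[a]), float(dist.probs[b])
    if pb == 0.0:
        raise ZeroDivisionError(f"choice probability of option {b} is zero")
    return pa / pb


def choice_difference(dist: ChoiceDistribution, a: int, b: int) -> float:
    """Difference P(a) - P(b) of two options' choice probabilities."""
    return float(dist.probs[a]) - float(dist.probs[b])
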