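"""Core BCV model: sequential Gaussian belief updating and incentive valuation.

The Bayesian model of context-sensitive value (BCV) assumes a decision maker
treats the reward amounts of the options on offer, attribute by attribute, as
samples from an unknown Gaussian population.  For each attribute ``i`` the
population mean ``C_i`` carries a Gaussian prior ``N(mu_C, sigma_C^2)`` and
each reward amount is observed with variance ``sigma_R^2``.  Rewards are
assimilated one at a time (sequential conjugate updating); the *incentive
value* of a reward is the precision-weighted prediction error computed at the
step it is considered::

    V(R) = g * (R - mu_hat),   g = var_hat / (var_hat + sigma_R^2)

where ``mu_hat`` / ``var_hat`` are the current posterior mean and variance of
the population average.  Option values sum the incentive values of an
option's rewards across attributes, and choice follows a softmax rule with
inverse temperature ``beta``.

This module is the pure single-trial computation; order randomisation,
Monte-Carlo averaging and the experiment drivers live in
:mod:`bcvsim.engine` and :mod:`bcvsim.experiments`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ChoiceProblem",
    "BCVParams",
    "BeliefState",
    "PresentationOrder",
    "ValuationTrace",
    "ChoiceDistribution",
    "expected_value",
    "gain",
    "update_belief",
    "evaluate_option_set",
    "softmax_choice",
]


def _as_1d(values, n: int, name: str) -> np.ndarray:
    """Broadcast a scalar or length-n sequence to a float array of length n."""
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if arr.size == 1:
        arr = np.full(n, arr.item())
    if arr.shape != (n,):
        raise ValueError(f"{name} must be a scalar or have length {n}, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass(frozen=True)
class ChoiceProblem:
    """A choice set: reward amounts indexed ``[attribute, option]``.

    ``rewards[i, n]`` is the reward amount the n-th option offers on the i-th
    attribute (arbitrary units).  Single-attribute problems have one row.
    """

    rewards: np.ndarray
    attribute_labels: tuple[str, ...] = ()
    option_labels: tuple[str, ...] = ()

    def __post_init__(self):
        rewards = np.atleast_2d(np.asarray(self.rewards, dtype=float))
        if rewards.ndim != 2 or rewards.size == 0:
            raise ValueError("rewards must be a nonempty (attributes x options) matrix")
        if not np.all(np.isfinite(rewards)):
            raise ValueError("all reward amounts must be finite")
        object.__setattr__(self, "rewards", rewards)
        n_attr, n_opt = rewards.shape
        attr = tuple(self.attribute_labels) or tuple(f"attr{i}" for i in range(n_attr))
        opt = tuple(self.option_labels) or tuple(f"option{n}" for n in range(n_opt))
        if len(attr) != n_attr:
            raise ValueError("attribute_labels length must match number of attributes")
        if len(opt) != n_opt:
            raise ValueError("option_labels length must match number of options")
        object.__setattr__(self, "attribute_labels", attr)
        object.__setattr__(self, "option_labels", opt)

    @property
    def n_attributes(self) -> int:
        return self.rewards.shape[0]

    @property
    def n_options(self) -> int:
        return self.rewards.shape[1]

    @classmethod
    def single_attribute(cls, rewards: Sequence[float],
                         option_labels: Sequence[str] = ()) -> "ChoiceProblem":
        """Build a one-attribute problem from a flat list of reward amounts."""
        return cls(np.asarray(rewards, dtype=float)[None, :],
                   option_labels=tuple(option_labels))


@dataclass(frozen=True)
class BCVParams:
    """Model parameters, broadcastable per attribute.

    Parameters
    ----------
    prior_mean
        Prior expectation mu_C of the population average reward, per attribute.
    prior_var
        Prior uncertainty sigma_C^2 (> 0), per attribute.
    reward_var
        Observation noise sigma_R^2 (> 0) of individual reward amounts,
        per attribute.  Small values magnify prediction errors and hence
        context effects.
    inverse_temperature
        Softmax inverse temperature beta (>= 0).
    """

    prior_mean: float | Sequence[float] = 0.0
    prior_var: float | Sequence[float] = 1.0
    reward_var: float | Sequence[float] = 1.0
    inverse_temperature: float = 1.0

    def __post_init__(self):
        if not np.isfinite(self.inverse_temperature) or self.inverse_temperature < 0:
            raise ValueError("inverse_temperature must be finite and >= 0")

    def per_attribute(self, n_attributes: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (prior_mean, prior_var, reward_var) arrays of length I."""
        mu = _as_1d(self.prior_mean, n_attributes, "prior_mean")
        var_c = _as_1d(self.prior_var, n_attributes, "prior_var")
        var_r = _as_1d(self.reward_var, n_attributes, "reward_var")
        if np.any(var_c <= 0):
            raise ValueError("prior_var must be > 0")
        if np.any(var_r <= 0):
            raise ValueError("reward_var must be > 0")
        return mu, var_c, var_r


@dataclass
class BeliefState:
    """Posterior mean and variance of one attribute's population average."""

    mean: float
    var: float

    def __post_init__(self):
        if not (np.isfinite(self.mean) and np.isfinite(self.var)):
            raise ValueError("belief mean and variance must be finite")
        if self.var <= 0:
            raise ValueError("belief variance must be > 0")


def expected_value(problem: ChoiceProblem, option: int) -> float:
    """Expected value of an option: the sum of its reward amounts over attributes."""
    if not (-problem.n_options <= option < problem.n_options):
        raise IndexError(f"option index {option} out of range for {problem.n_options} options")
    return float(problem.rewards[:, option].sum())


def gain(prior_var: float, obs_var: float) -> float:
    """Precision weight ``prior_var / (prior_var + obs_var)``, in (0, 1).

    This is the Kalman-type gain applied to a prediction error: it grows with
    prior uncertainty and shrinks with observation noise.
    """
    if not (np.isfinite(prior_var) and prior_var > 0):
        raise ValueError("prior_var must be finite and > 0")
    if not (np.isfinite(obs_var) and obs_var > 0):
        raise ValueError("obs_var must be finite and > 0")
    return prior_var / (prior_var + obs_var)


def update_belief(state: BeliefState, reward: float,
                  reward_var: float) -> tuple[BeliefState, float]:
    """One conjugate-Gaussian update; returns the new belief and incentive value.

    The incentive value is the precision-weighted prediction error
    ``g * (reward - state.mean)``; the posterior mean shifts by exactly this
    amount and the posterior variance contracts by the factor ``(1 - g)``.
    """
    if not np.isfinite(reward):
        raise ValueError("reward must be finite")
    g = gain(state.var, reward_var)
    value = g * (reward - state.mean)
    new_state = BeliefState(mean=state.mean + value, var=state.var - g * state.var)
    return new_state, value


@dataclass(frozen=True)
class PresentationOrder:
    """Per-attribute permutations giving the order options are considered in.

    ``orders[i]`` is a permutation of option indices for attribute ``i``;
    orders may differ across attributes.
    """

    orders: np.ndarray  # (I, N) integer matrix, each row a permutation of 0..N-1

    def __post_init__(self):
        orders = np.atleast_2d(np.asarray(self.orders, dtype=np.intp))
        expected = np.arange(orders.shape[1])
        for row in orders:
            if not np.array_equal(np.sort(row), expected):
                raise ValueError(f"order {row.tolist()} is not a permutation of 0..{orders.shape[1] - 1}")
        object.__setattr__(self, "orders", orders)

    @classmethod
    def identity(cls, n_attributes: int, n_options: int) -> "PresentationOrder":
        return cls(np.tile(np.arange(n_options), (n_attributes, 1)))

    @classmethod
    def random(cls, rng: np.random.Generator, n_attributes: int,
               n_options: int) -> "PresentationOrder":
        """Uniform independent permutation per attribute."""
        return cls(np.stack([rng.permutation(n_options) for _ in range(n_attributes)]))


@dataclass(frozen=True)
class ValuationTrace:
    """Full record of one sequential valuation pass over a choice set.

    ``step_values[i, n]`` is the incentive value attributed to option ``n``'s
    reward on attribute ``i`` at the step it was considered.  Option values
    sum step values over attributes; per attribute the step values telescope
    to (final posterior mean - prior mean).
    """

    orders: PresentationOrder
    step_values: np.ndarray   # (I, N), indexed by option (not by step position)
    option_values: np.ndarray  # (N,)
    final_beliefs: tuple[BeliefState, ...]


def evaluate_option_set(problem: ChoiceProblem, params: BCVParams,
                        orders: PresentationOrder) -> ValuationTrace:
    """Run sequential belief updating over a full choice set.

    Each attribute is processed independently (the generative model assumes
    independent reward populations per attribute), starting from its prior
    and assimilating the option rewards in the given presentation order.
    Deterministic given ``orders``.
    """
    n_attr, n_opt = problem.n_attributes, problem.n_options
    if orders.orders.shape != (n_attr, n_opt):
        raise ValueError(
            f"presentation order shape {orders.orders.shape} does not match "
            f"problem shape {(n_attr, n_opt)}")
    mu, var_c, var_r = params.per_attribute(n_attr)

    step_values = np.zeros((n_attr, n_opt))
    final_beliefs: list[BeliefState] = []
    for i in range(n_attr):
        state = BeliefState(mean=mu[i], var=var_c[i])
        for n in orders.orders[i]:
            state, value = update_belief(state, problem.rewards[i, n], var_r[i])
            step_values[i, n] = value
        final_beliefs.append(state)

    return ValuationTrace(
        orders=orders,
        step_values=step_values,
        option_values=step_values.sum(axis=0),
        final_beliefs=tuple(final_beliefs),
    )


@dataclass(frozen=True)
class ChoiceDistribution:
    """Choice probabilities per option, with standard errors for MC estimates."""

    probs: np.ndarray
    stderr: np.ndarray
    method: str  # "exact" or "monte_carlo"

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        stderr = np.asarray(self.stderr, dtype=float)
        if probs.ndim != 1 or probs.size == 0:
            raise ValueError("probs must be a nonempty 1-D array")
        if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")
        if stderr.shape != probs.shape or np.any(stderr < 0):
            raise ValueError("stderr must be nonnegative and match probs")
        if self.method not in ("exact", "monte_carlo"):
            raise ValueError("method must be 'exact' or 'monte_carlo'")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "stderr", stderr)


def softmax_choice(option_values: Sequence[float], beta: float) -> ChoiceDistribution:
    """Softmax choice rule: P(n) proportional to exp(beta * V_n).

    Overflow-safe (max subtraction).  ``beta = 0`` yields the uniform
    distribution.
    """
    values = np.asarray(option_values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("option_values must be a nonempty 1-D sequence")
    if not np.all(np.isfinite(values)):
        raise ValueError("option_values must be finite")
    if not np.isfinite(beta) or beta < 0:
        raise ValueError("beta must be finite and >= 0")
    z = beta * values
    z = z - z.max()
    ez = np.exp(z)
    probs = ez / ez.sum()
    return ChoiceDistribution(probs=probs, stderr=np.zeros_like(probs), method="exact")
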