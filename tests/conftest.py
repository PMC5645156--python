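"""Shared fixtures and an independent brute-force oracle for choice probabilities."""

import itertools

import numpy as np
import pytest

from bcvsim import BCVParams, ChoiceProblem


def brute_force_choice_probs(rewards, mu, sigma_C2, sigma_R2, beta):
    """Choice probabilities by naive enumeration, written independently of the
    engine: explicit per-order sequential updating with scalar loops, softmax
    averaged over all per-attribute order combinations."""
    rewards = np.atleast_2d(np.asarray(rewards, dtype=float))
    n_attr, n_opt = rewards.shape
    perms = list(itertools.permutations(range(n_opt)))
    total = np.zeros(n_opt)
    combos = list(itertools.product(perms, repeat=n_attr))
    for combo in combos:
        values = np.zeros(n_opt)
        for i in range(n_attr):
            mean, var = mu, sigma_C2
            for n in combo[i]:
                g = var / (var + sigma_R2)
                pe = g * (rewards[i, n] - mean)
                values[n] += pe
                mean += pe
                var -= g * var
        z = beta * values
        e = np.exp(z - z.max())
        total += e / e.sum()
    return total / len(combos)


@pytest.fixture
def binary_problem():
    """The standard single-attribute high/low pair (10 vs 6)."""
    return ChoiceProblem.single_attribute([10.0, 6.0], option_labels=("H", "L"))


@pytest.fixture
def sharp_params():
    """Default parameters with small reward uncertainty (strong context effects)."""
    return BCVParams(prior_mean=0.0, prior_var=1.0, reward_var=0.1,
                     inverse_temperature=1.0)
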