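"""Between-choice context models: contextual observations at one or two levels.

Here context effects arise not from the other options in the current choice
set but from expectations established before the option appears.  A
contextual cue ``O`` (e.g. the block, deck or restaurant the agent is in) is
a noisy observation of the same hidden population mean ``C`` that generates
rewards.  The agent first infers ``C`` from ``O`` and then values a reward
``R`` by the precision-weighted prediction error against that
context-informed expectation — so the same reward is worth less where more
was expected (subtractive normalization), scaled by a gain in (0,1)
(divisive normalization).

The two-level model stacks a high-level context HC (e.g. a neighbourhood)
above a low-level context LC (e.g. a restaurant), each with its own noisy
observation (HO, LO).  Sequential conjugate inference collapses to the
closed form::

    V(R) = K * (R - tau_LO * LO - tau_HO * HO)

with three normalization factors in (0,1): two subtractive weights tau_LO,
tau_HO giving the relative precision of the two contextual cues, and the
divisive gain K.  When LO is known precisely (sigma_LO^2 -> 0) the low-level
context screens off the high level (tau_HO -> 0): a Markov-blanket effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core import BeliefState, gain

__all__ = [
    "SingleLevelContextModel",
    "HierarchicalContextModel",
    "NormalizationFactors",
    "ContextScenario",
    "single_level_value",
    "hierarchical_factors",
    "hierarchical_value",
    "hierarchical_value_sequential",
    "scenario_predictions",
    "magnitude_scenario",
    "variance_scenario",
    "two_level_scenario",
]


def _check_var(value: float, name: str) -> float:
    value = float(value)
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be finite and > 0")
    return value


@dataclass(frozen=True)
class SingleLevelContextModel:
    """One contextual observation O ~ N(C, sigma_O^2) above the reward level.

    The prior over the population mean C is N(0, prior_var); rewards are
    observed with variance reward_var.
    """

    prior_var: float = 1.0
    context_obs_var: float = 1.0
    reward_var: float = 1.0

    def __post_init__(self):
        _check_var(self.prior_var, "prior_var")
        _check_var(self.context_obs_var, "context_obs_var")
        _check_var(self.reward_var, "reward_var")


def single_level_value(O: float, R: float, model: SingleLevelContextModel,
                       prior_mean: float = 0.0) -> tuple[float, BeliefState]:
    """Incentive value of reward R given contextual observation O.

    The context posterior has mean ``g_O * O`` (with ``prior_mean = 0``; a
    nonzero mean generalises as ``mu + g_O*(O - mu)``) and contracted
    variance; the value is the precision-weighted prediction error of R
    against it.  Returns ``(value, context_posterior)``.
    """
    if not (np.isfinite(O) and np.isfinite(R) and np.isfinite(prior_mean)):
        raise ValueError("O, R and prior_mean must be finite")
    g_o = gain(model.prior_var, model.context_obs_var)
    mu_post = prior_mean + g_o * (O - prior_mean)
    var_post = model.prior_var - g_o * model.prior_var
    value = gain(var_post, model.reward_var) * (R - mu_post)
    return value, BeliefState(mean=mu_post, var=var_post)


@dataclass(frozen=True)
class HierarchicalContextModel:
    """Two-level context: HC -> (HO, LC), LC -> (LO, R); prior mean of HC is 0."""

    var_hc: float = 1.0
    var_ho: float = 1.0
    var_lc: float = 1.0
    var_lo: float = 1.0
    var_r: float = 1.0

    def __post_init__(self):
        for name in ("var_hc", "var_ho", "var_lc", "var_lo", "var_r"):
            _check_var(getattr(self, name), name)


@dataclass(frozen=True)
class NormalizationFactors:
    """The three normalization factors of the two-level closed form.

    ``tau_lo`` and ``tau_ho`` weight the subtractive contributions of the
    low- and high-level contextual observations; ``k`` is the divisive gain
    on the resulting prediction error.  Each lies strictly in (0,1) for
    finite positive variances.
    """

    tau_lo: float
    tau_ho: float
    k: float


def hierarchical_factors(model: HierarchicalContextModel) -> NormalizationFactors:
    """Normalization factors from the model variances.

    Sequential conjugate inference gives the posterior variance of LC after
    HO (the high-level posterior variance plus the level-coupling variance),
    then after LO; the factors are precision ratios of those posteriors.
    """
    var_hc_post = model.var_hc - gain(model.var_hc, model.var_ho) * model.var_hc
    var_lc_given_ho = var_hc_post + model.var_lc
    g_lo = gain(var_lc_given_ho, model.var_lo)
    var_lc_post = var_lc_given_ho - g_lo * var_lc_given_ho
    tau_lo = g_lo
    tau_ho = (model.var_lo / (var_lc_given_ho + model.var_lo)) \
        * gain(model.var_hc, model.var_ho)
    k = gain(var_lc_post, model.var_r)
    return NormalizationFactors(tau_lo=tau_lo, tau_ho=tau_ho, k=k)


def hierarchical_value(HO: float, LO: float, R: float,
                       model: HierarchicalContextModel) -> float:
    """Incentive value K*(R - tau_LO*LO - tau_HO*HO) under the two-level model."""
    if not (np.isfinite(HO) and np.isfinite(LO) and np.isfinite(R)):
        raise ValueError("HO, LO and R must be finite")
    f = hierarchical_factors(model)
    return f.k * (R - f.tau_lo * LO - f.tau_ho * HO)


def hierarchical_value_sequential(HO: float, LO: float, R: float,
                                  model: HierarchicalContextModel) -> float:
    """Same value computed by explicit step-by-step posterior updates.

    Infers P(HC|HO), P(LC|HO), P(LC|HO,LO) in sequence and returns the
    precision-weighted prediction error of R at the last step.  Algebraically
    identical to :func:`hierarchical_value`; kept as an independent route for
    consistency checks.
    """
    g_ho = gain(model.var_hc, model.var_ho)
    mu_hc = g_ho * HO
    var_hc = model.var_hc - g_ho * model.var_hc
    # LC inherits HC's posterior mean; variance adds the coupling term
    mu_lc, var_lc = mu_hc, var_hc + model.var_lc
    g_lo = gain(var_lc, model.var_lo)
    mu_lc = mu_lc + g_lo * (LO - mu_lc)
    var_lc = var_lc - g_lo * var_lc
    return gain(var_lc, model.var_r) * (R - mu_lc)


@dataclass(frozen=True)
class ContextScenario:
    """Reward menus per context, at one or (optionally) two hierarchical levels.

    ``offsets`` maps each (low-level) context label to the rewards it can
    deliver, expressed as offsets from the base value; the realised reward
    list is ``base + offset``.  For a two-level scenario, ``groups`` maps
    each high-level context label to the low-level contexts it contains.

    Rewards are expressed relative to the agent's baseline reward
    expectation (the model's zero prior mean), so scenario menus should
    straddle zero; the default base of -1.5 centres the standard menus.
    """

    name: str
    offsets: Mapping[str, tuple[float, ...]]
    groups: Mapping[str, tuple[str, ...]] | None = None
    base: float = -1.5

    def __post_init__(self):
        if not self.offsets:
            raise ValueError("scenario must define at least one context")
        offsets = {str(k): tuple(float(x) for x in v) for k, v in self.offsets.items()}
        if any(len(v) == 0 for v in offsets.values()):
            raise ValueError("every context must offer at least one reward")
        object.__setattr__(self, "offsets", offsets)
        if self.groups is not None:
            groups = {str(k): tuple(str(x) for x in v) for k, v in self.groups.items()}
            if not groups:
                raise ValueError("groups, if given, must be nonempty")
            unknown = {c for members in groups.values() for c in members} - set(offsets)
            if unknown:
                raise ValueError(f"groups refer to unknown contexts: {sorted(unknown)}")
            object.__setattr__(self, "groups", groups)

    def rewards(self, context: str) -> np.ndarray:
        return self.base + np.asarray(self.offsets[context], dtype=float)


def magnitude_scenario(base: float = -1.5) -> ContextScenario:
    """Low-average vs high-average context: menus {x,x+1,x+2} and {x+1,x+2,x+3}."""
    return ContextScenario("magnitude", {"LA": (0, 1, 2), "HA": (1, 2, 3)}, base=base)


def variance_scenario(base: float = -1.5) -> ContextScenario:
    """High-variance vs low-variance context with equal means:
    menus {x,x+1,x+2,x+3} and {x+1,x+2}."""
    return ContextScenario("variance", {"HV": (0, 1, 2, 3), "LV": (1, 2)}, base=base)


def two_level_scenario(base: float = -1.5) -> ContextScenario:
    """Two-level deck/deck-set scenario: low-, medium- and high-average decks
    grouped into a low-value and a high-value deck set."""
    return ContextScenario(
        "two-level",
        {"LL-LA": (0, 1, 2), "LL-MA": (1, 2, 3), "LL-HA": (2, 3, 4)},
        groups={"HL-LA": ("LL-LA", "LL-MA"), "HL-HA": ("LL-MA", "LL-HA")},
        base=base)


def scenario_predictions(scenario: ContextScenario,
                         prior_var: float = 1.0,
                         obs_var: float = 1.0,
                         reward_var_floor: float = 0.01) -> pd.DataFrame:
    """Incentive value of every reward in every context of a scenario.

    A context's observation (O, or LO/HO at two levels) is the mean of its
    reward menu; its reward variance is the population variance of the menu,
    floored at ``reward_var_floor``.  Single-level contexts use
    :func:`single_level_value`; grouped contexts use
    :func:`hierarchical_value` with the high-level observation set to the
    mean over the group's pooled menu.  Returns a long table with columns
    ``context``, ``hl_context`` (two-level only), ``offset``, ``reward``,
    ``value`` suitable for ordinal comparisons.
    """
    _check_var(prior_var, "prior_var")
    _check_var(obs_var, "obs_var")
    records = []
    if scenario.groups is None:
        for context in scenario.offsets:
            rewards = scenario.rewards(context)
            model = SingleLevelContextModel(
                prior_var=prior_var, context_obs_var=obs_var,
                reward_var=max(float(rewards.var()), reward_var_floor))
            O = float(rewards.mean())
            for off, r in zip(scenario.offsets[context], rewards):
                value, _ = single_level_value(O, float(r), model)
                records.append(dict(context=context, hl_context=None,
                                    offset=off, reward=float(r), value=value))
    else:
        for hl, members in scenario.groups.items():
            pooled = np.concatenate([scenario.rewards(c) for c in members])
            HO = float(pooled.mean())
            for context in members:
                rewards = scenario.rewards(context)
                model = HierarchicalContextModel(
                    var_hc=prior_var, var_ho=obs_var,
                    var_lc=prior_var, var_lo=obs_var,
                    var_r=max(float(rewards.var()), reward_var_floor))
                LO = float(rewards.mean())
                for off, r in zip(scenario.offsets[context], rewards):
                    records.append(dict(
                        context=context, hl_context=hl, offset=off,
                        reward=float(r),
                        value=hierarchical_value(HO, LO, float(r), model)))
    return pd.DataFrame.from_records(
        records, columns=["context", "hl_context", "offset", "reward", "value"])
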