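"""Unit and property tests for the single-trial valuation core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcvsim import (
    BCVParams,
    BeliefState,
    ChoiceProblem,
    PresentationOrder,
    evaluate_option_set,
    expected_value,
    gain,
    softmax_choice,
    update_belief,
)


class TestExpectedValue:
    @pytest.mark.parametrize("rewards, option, expected", [
        ([[1.0, 10.0], [10.0, 1.0]], 0, 11.0),   # car A: price 1 + quality 10
        ([[6.0]], 0, 6.0),
        ([[0.0], [0.0]], 0, 0.0),
    ])
    def test_sums_rewards_over_attributes(self, rewards, option, expected):
        assert expected_value(ChoiceProblem(np.array(rewards)), option) == expected

    def test_invalid_index_raises(self):
        with pytest.raises(IndexError):
            expected_value(ChoiceProblem.single_attribute([1.0, 2.0]), 5)


class TestGain:
    @pytest.mark.parametrize("prior_var, obs_var, expected", [
        (1.0, 1.0, 0.5),
        (1.0, 0.1, 1 / 1.1),
        (1.0, 10.0, 1 / 11),
    ])
    def test_values(self, prior_var, obs_var, expected):
        assert gain(prior_var, obs_var) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("prior_var, obs_var", [(0.0, 1.0), (1.0, 0.0),
                                                    (-1.0, 1.0), (1.0, -2.0)])
    def test_nonpositive_variance_rejected(self, prior_var, obs_var):
        with pytest.raises(ValueError):
            gain(prior_var, obs_var)

    @given(st.floats(0.01, 100), st.floats(0.01, 100), st.floats(1.01, 3))
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_monotonicity(self, prior_var, obs_var, factor):
        g = gain(prior_var, obs_var)
        assert 0 < g < 1
        assert gain(prior_var, obs_var * factor) < g        # noisier data
        assert gain(prior_var * factor, obs_var) > g        # vaguer prior


class TestUpdateBelief:
    def test_zero_prediction_error(self):
        state, value = update_belief(BeliefState(0.0, 1.0), 0.0, 0.1)
        assert value == 0.0
        assert state.mean == 0.0

    def test_first_update_hand_values(self):
        state, value = update_belief(BeliefState(0.0, 1.0), 10.0, 0.1)
        assert value == pytest.approx(10 / 1.1, abs=1e-10)
        assert state.mean == pytest.approx(10 / 1.1, abs=1e-10)
        assert state.var == pytest.approx(0.1 / 1.1, abs=1e-10)

    def test_second_update_hand_values(self):
        state = BeliefState(9.090909, 0.090909)
        _, value = update_belief(state, 6.0, 0.1)
        g = 0.090909 / 0.190909
        assert value == pytest.approx(g * (6 - 9.090909), abs=1e-6)
        assert value == pytest.approx(-1.471861, abs=1e-5)

    def test_nonfinite_reward_rejected(self):
        with pytest.raises(ValueError):
            update_belief(BeliefState(0.0, 1.0), float("nan"), 0.1)

    def test_incentive_value_shrinks_with_reward_noise(self):
        # the same prediction error is weighted down as sigma_R^2 grows
        values = [update_belief(BeliefState(0.0, 1.0), 5.0, sr2)[1]
                  for sr2 in (0.1, 1.0, 10.0)]
        assert values[0] > values[1] > values[2] > 0


class TestEvaluateOptionSet:
    def test_chained_hand_example(self, binary_problem, sharp_params):
        trace = evaluate_option_set(binary_problem, sharp_params,
                                    PresentationOrder(np.array([[0, 1]])))
        assert trace.option_values[0] == pytest.approx(9.090909, abs=1e-6)
        assert trace.option_values[1] == pytest.approx(-1.471861, abs=1e-6)

    def test_rewards_at_prior_mean_give_zero_values(self):
        problem = ChoiceProblem(np.full((2, 3), 4.0))
        params = BCVParams(prior_mean=4.0, prior_var=1.0, reward_var=0.5)
        trace = evaluate_option_set(problem, params,
                                    PresentationOrder.identity(2, 3))
        assert np.allclose(trace.option_values, 0.0, atol=1e-12)

    def test_posterior_is_order_invariant_but_values_are_not(self, binary_problem,
                                                             sharp_params):
        t1 = evaluate_option_set(binary_problem, sharp_params,
                                 PresentationOrder(np.array([[0, 1]])))
        t2 = evaluate_option_set(binary_problem, sharp_params,
                                 PresentationOrder(np.array([[1, 0]])))
        assert t1.final_beliefs[0].mean == pytest.approx(t2.final_beliefs[0].mean,
                                                         abs=1e-10)
        assert t1.final_beliefs[0].var == pytest.approx(t2.final_beliefs[0].var,
                                                        abs=1e-10)
        assert not np.allclose(t1.step_values, t2.step_values)

    def test_step_values_telescope_to_posterior_shift(self):
        rng = np.random.default_rng(7)
        problem = ChoiceProblem(rng.normal(2.0, 3.0, size=(3, 4)))
        params = BCVParams(prior_mean=[0.0, 1.0, -1.0], prior_var=2.0,
                           reward_var=[0.5, 1.0, 3.0])
        orders = PresentationOrder.random(rng, 3, 4)
        trace = evaluate_option_set(problem, params, orders)
        mu, _, _ = params.per_attribute(3)
        for i in range(3):
            assert trace.step_values[i].sum() == pytest.approx(
                trace.final_beliefs[i].mean - mu[i], abs=1e-10)

    def test_variance_contraction_closed_form(self):
        # posterior variance after t updates is 1/(1/sigma_C^2 + t/sigma_R^2)
        sc2, sr2, n = 2.0, 0.7, 5
        problem = ChoiceProblem.single_attribute(np.linspace(-3, 3, n))
        params = BCVParams(0.0, sc2, sr2)
        trace = evaluate_option_set(problem, params, PresentationOrder.identity(1, n))
        assert trace.final_beliefs[0].var == pytest.approx(
            1.0 / (1.0 / sc2 + n / sr2), abs=1e-10)

    def test_translation_invariance(self, sharp_params):
        rng = np.random.default_rng(3)
        rewards = rng.normal(0, 2, size=(2, 3))
        orders = PresentationOrder.random(rng, 2, 3)
        shift = 7.3
        t0 = evaluate_option_set(ChoiceProblem(rewards), sharp_params, orders)
        shifted = BCVParams(prior_mean=shift, prior_var=1.0, reward_var=0.1)
        t1 = evaluate_option_set(ChoiceProblem(rewards + shift), shifted, orders)
        assert np.allclose(t0.step_values, t1.step_values, atol=1e-10)

    def test_incentive_value_increases_with_own_reward(self, sharp_params):
        orders = PresentationOrder(np.array([[0, 1, 2]]))
        values = []
        for r in (4.0, 5.0, 6.0):
            problem = ChoiceProblem.single_attribute([2.0, r, 8.0])
            trace = evaluate_option_set(problem, sharp_params, orders)
            values.append(trace.step_values[0, 1])
        assert values[0] < values[1] < values[2]

    def test_bad_order_shape_rejected(self, binary_problem, sharp_params):
        with pytest.raises(ValueError):
            evaluate_option_set(binary_problem, sharp_params,
                                PresentationOrder(np.array([[0, 1], [1, 0]])))

    def test_non_permutation_rejected(self):
        with pytest.raises(ValueError):
            PresentationOrder(np.array([[0, 0]]))


class TestSoftmaxChoice:
    def test_equal_values_uniform(self):
        dist = softmax_choice([3.0, 3.0, 3.0], 1.0)
        assert np.allclose(dist.probs, 1 / 3, atol=1e-12)

    def test_zero_beta_uniform(self):
        dist = softmax_choice([-5.0, 0.0, 40.0], 0.0)
        assert np.allclose(dist.probs, 1 / 3, atol=1e-12)

    def test_hand_value(self):
        dist = softmax_choice([9.090909, -1.471861], 1.0)
        assert dist.probs[0] == pytest.approx(1 / (1 + np.exp(-10.562770)), abs=1e-9)
        assert dist.probs[0] == pytest.approx(0.999974, abs=1e-6)

    def test_overflow_safe(self):
        dist = softmax_choice([1e4, 0.0], 1.0)
        assert dist.probs[0] == pytest.approx(1.0, abs=1e-12)
        assert np.isfinite(dist.probs).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            softmax_choice([], 1.0)

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=6),
           st.floats(0, 5))
    @settings(max_examples=50, deadline=None)
    def test_simplex(self, values, beta):
        dist = softmax_choice(values, beta)
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert (dist.probs >= 0).all()


class TestValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(prior_var=0.0), dict(prior_var=-1.0),
        dict(reward_var=0.0), dict(reward_var=-0.5),
    ])
    def test_degenerate_variances_rejected(self, kwargs, binary_problem):
        params = BCVParams(**kwargs)
        with pytest.raises(ValueError):
            params.per_attribute(binary_problem.n_attributes)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            BCVParams(inverse_temperature=-0.1)

    def test_nonfinite_rewards_rejected(self):
        with pytest.raises(ValueError):
            ChoiceProblem(np.array([[1.0, np.inf]]))
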