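"""Value functions, choice rules, likelihoods and their invariances."""

import itertools

import numpy as np
import pytest

from itchoice import (ItemSet, MODEL_IDS, ParameterVector, choice_prob_ll,
                      dataset_loglik, discounted_value, get_model,
                      simulate_choices)
from itchoice.models import AttributeWiseError

from conftest import MODEL_PARAMS, random_items

DU_MULTIPLICATIVE = ("exponential", "hyperbolic", "double_exponential",
                     "generalized_hyperbolic", "hyperboloid",
                     "generalized_hyperbola", "constant_sensitivity")
ATTRIBUTE_WISE = ("proportional_difference", "itch", "tradeoff")


class TestDiscountedValue:
    @pytest.mark.parametrize("model_id,params,x,t,expected", [
        ("hyperbolic", {"k": 0.1, "sigma": 1.0}, 100, 10, 50.0),
        ("exponential", {"k": 0.0, "sigma": 1.0}, 80, 186, 80.0),
        ("generalized_hyperbolic", {"k": 0.05, "s": 1.0, "sigma": 1.0},
         60, 20, 30.0),
        ("constant_sensitivity", {"alpha": 0.02, "beta": 1.0, "sigma": 1.0},
         100, 10, 100 * np.exp(-0.2)),
    ])
    def test_closed_forms(self, model_id, params, x, t, expected):
        assert discounted_value(model_id, params, x, t) == pytest.approx(
            expected, rel=1e-12)

    @pytest.mark.parametrize("model_id", DU_MULTIPLICATIVE)
    def test_multiplicative_value_bounded_by_amount(self, model_id, rng):
        x, t = rng.uniform(1, 100, 50), rng.uniform(0, 200, 50)
        v = discounted_value(model_id, MODEL_PARAMS[model_id], x, t)
        assert np.all(v >= 0) and np.all(v <= x)

    def test_additive_utility_can_go_negative(self):
        v = discounted_value("additive_utility", MODEL_PARAMS["additive_utility"],
                             2.0, 2000.0)
        assert v < 0

    @pytest.mark.parametrize("model_id", ATTRIBUTE_WISE)
    def test_attribute_wise_has_no_per_option_value(self, model_id):
        with pytest.raises(AttributeWiseError):
            discounted_value(model_id, MODEL_PARAMS[model_id], 100, 10)

    def test_unknown_model_rejected(self):
        with pytest.raises(KeyError, match="unknown model_id"):
            discounted_value("quasi_hyperbolic", {"k": 1}, 100, 10)


class TestChoiceProbability:
    def test_equal_values_give_half_for_du_models(self):
        # exponential item built to have exactly equal discounted values
        k = 0.1
        item = ItemSet(x_ss=[50.0], t_ss=[0.0],
                       x_ll=[50.0 * np.exp(k * 10)], t_ll=[10.0])
        for sigma in (0.01, 1.0, 50.0):
            p = choice_prob_ll("exponential", {"k": k, "sigma": sigma}, item)
            assert p[0] == pytest.approx(0.5, abs=1e-12)

    def test_proportional_difference_threshold_at_d(self):
        item = ItemSet(x_ss=[50.0], t_ss=[0.0], x_ll=[100.0], t_ll=[10.0])
        # d = 0.5 - 1 = -0.5; immediate SS makes the delay term exactly 1
        for sigma in (0.5, 2.0, 10.0):
            p = choice_prob_ll("proportional_difference",
                               {"delta": -0.5, "sigma": sigma}, item)
            assert p[0] == pytest.approx(0.5, abs=1e-12)

    def test_itch_all_zero_weights_give_half(self, rng):
        items = random_items(rng, 30)
        params = {n: 0.0 for n in get_model("itch").param_names}
        assert np.allclose(choice_prob_ll("itch", params, items), 0.5)

    def test_tradeoff_small_gamma_tau_limit(self):
        # gamma, tau -> 0: v -> x and w -> t; compare to the closed form
        item = ItemSet(x_ss=[30.0], t_ss=[5.0], x_ll=[80.0], t_ll=[45.0])
        kappa, alpha, theta, eps = 1.5, 1.0, 1.5, 0.3
        p = choice_prob_ll("tradeoff",
                           {"gamma": 1e-9, "tau": 1e-9, "kappa": kappa,
                            "alpha": alpha, "theta": theta, "eps": eps}, item)
        q_v = 80.0 - 30.0
        q_w = (kappa / alpha) * np.log1p(alpha * ((45.0 - 5.0) / theta) ** theta)
        expected = q_v ** (1 / eps) / (q_v ** (1 / eps) + q_w ** (1 / eps))
        assert p[0] == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_probabilities_strictly_inside_unit_interval(self, model_id, rng):
        p = choice_prob_ll(model_id, MODEL_PARAMS[model_id], random_items(rng, 50))
        assert np.all(p > 0) and np.all(p < 1)


class TestReductionIdentities:
    """Nested models must collapse onto their parents exactly."""

    def _probs(self, model_id, params, items):
        return choice_prob_ll(model_id, params, items)

    @pytest.mark.parametrize("reduced,parent", [
        (("generalized_hyperbolic", {"k": 0.07, "s": 1.0, "sigma": 0.2}),
         ("hyperbolic", {"k": 0.07, "sigma": 0.2})),
        (("hyperboloid", {"k": 0.07, "s": 1.0, "sigma": 0.2}),
         ("hyperbolic", {"k": 0.07, "sigma": 0.2})),
        (("generalized_hyperbola", {"alpha": 0.07, "beta": 0.07, "sigma": 0.2}),
         ("hyperbolic", {"k": 0.07, "sigma": 0.2})),
        (("constant_sensitivity", {"alpha": 0.03, "beta": 1.0, "sigma": 0.2}),
         ("exponential", {"k": 0.03, "sigma": 0.2})),
        (("double_exponential", {"beta": 0.03, "delta": 0.005, "omega": 1.0,
                                 "sigma": 0.2}),
         ("exponential", {"k": 0.03, "sigma": 0.2})),
        (("double_exponential", {"beta": 0.03, "delta": 0.03, "omega": 0.35,
                                 "sigma": 0.2}),
         ("exponential", {"k": 0.03, "sigma": 0.2})),
    ])
    def test_identity(self, reduced, parent, rng):
        items = random_items(rng, 60)
        p_red = self._probs(reduced[0], reduced[1], items)
        p_par = self._probs(parent[0], parent[1], items)
        np.testing.assert_allclose(p_red, p_par, atol=1e-10, rtol=0)


class TestEffectInvariances:
    @pytest.mark.parametrize("model_id", DU_MULTIPLICATIVE)
    @pytest.mark.parametrize("c", [0.1, 3.0, 50.0])
    def test_magnitude_scaling_preserves_preference_sign(self, model_id, c, rng):
        items = random_items(rng, 40)
        scaled = ItemSet(items.x_ss * c, items.t_ss, items.x_ll * c,
                         items.t_ll, items.time_unit)
        p0 = choice_prob_ll(model_id, MODEL_PARAMS[model_id], items)
        p1 = choice_prob_ll(model_id, MODEL_PARAMS[model_id], scaled)
        np.testing.assert_array_equal(np.sign(p0 - 0.5), np.sign(p1 - 0.5))

    def test_exponential_common_delay_invariance(self, rng):
        items = random_items(rng, 40)
        p0 = choice_prob_ll("exponential", MODEL_PARAMS["exponential"], items)
        for delta in (5.0, 60.0):
            shifted = ItemSet(items.x_ss, items.t_ss + delta, items.x_ll,
                              items.t_ll + delta, items.time_unit)
            p1 = choice_prob_ll("exponential", MODEL_PARAMS["exponential"],
                                shifted)
            np.testing.assert_array_equal(np.sign(p0 - 0.5), np.sign(p1 - 0.5))

    def test_hyperbolic_common_delay_monotone_single_crossing(self):
        item = {"x_ss": 40.0, "x_ll": 60.0, "t_ss": 0.0, "t_ll": 30.0}
        params = {"k": 0.05, "sigma": 1.0}
        deltas = np.linspace(0, 300, 200)
        dv = np.array([
            discounted_value("hyperbolic", params, item["x_ll"], item["t_ll"] + d)
            - discounted_value("hyperbolic", params, item["x_ss"], item["t_ss"] + d)
            for d in deltas])
        # the utility advantage changes sign at most once, SS- to LL-preferred
        # (it is not globally monotone: after the crossing both values decay
        # to zero, so the positive advantage shrinks back toward 0+)
        sign_changes = np.sum(np.diff(np.sign(dv[dv != 0])) != 0)
        assert sign_changes <= 1
        assert dv[0] < 0 < dv[-1]
        # monotone non-decreasing up to the crossing
        crossing = np.argmax(dv > 0)
        assert np.all(np.diff(dv[:crossing + 1]) >= -1e-12)

    def test_proportional_difference_delay_scaling_invariance(self, rng):
        from itchoice.models import ProportionalDifference
        items = random_items(rng, 40)
        items = items.take(np.where(items.t_ss > 0)[0])
        d0 = ProportionalDifference.prop_difference(items)
        for c in (0.5, 7.0):
            scaled = ItemSet(items.x_ss, items.t_ss * c, items.x_ll,
                             items.t_ll * c, items.time_unit)
            np.testing.assert_allclose(
                ProportionalDifference.prop_difference(scaled), d0, atol=1e-12)

    def test_proportional_difference_immediate_ss_ignores_delay(self):
        from itchoice.models import ProportionalDifference
        base = dict(x_ss=[50.0], t_ss=[0.0], x_ll=[100.0])
        d = [ProportionalDifference.prop_difference(
            ItemSet(t_ll=[t], **base))[0] for t in (1.0, 10.0, 500.0)]
        assert d[0] == d[1] == d[2]  # delay term is 1/1 whenever t_ss = 0


class TestDatasetLoglik:
    def test_two_half_probability_items(self):
        items = ItemSet(x_ss=[50.0, 50.0], t_ss=[0.0, 0.0],
                        x_ll=[100.0, 100.0], t_ll=[10.0, 10.0])
        params = {n: 0.0 for n in get_model("itch").param_names}
        for choices in ([0, 0], [0, 1], [1, 1]):
            ll = dataset_loglik("itch", params, items, np.array(choices))
            assert ll == pytest.approx(2 * np.log(0.5))

    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_probabilities_sum_to_one_over_response_patterns(self, model_id,
                                                            two_items):
        total = 0.0
        for pattern in itertools.product([0, 1], repeat=2):
            total += np.exp(dataset_loglik(model_id, MODEL_PARAMS[model_id],
                                           two_items, np.array(pattern)))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_empty_dataset_is_zero(self):
        empty = ItemSet(x_ss=[], t_ss=[], x_ll=[], t_ll=[])
        assert dataset_loglik("hyperbolic", MODEL_PARAMS["hyperbolic"],
                              empty, np.array([])) == 0.0

    def test_invalid_choice_codes_rejected(self, two_items):
        with pytest.raises(ValueError, match="choice codes"):
            dataset_loglik("hyperbolic", MODEL_PARAMS["hyperbolic"],
                           two_items, np.array([0, 2]))

    def test_loglik_never_positive(self, rng):
        items = random_items(rng, 30)
        for model_id in MODEL_IDS:
            ch = simulate_choices(model_id, MODEL_PARAMS[model_id], items, 3)
            assert dataset_loglik(model_id, MODEL_PARAMS[model_id],
                                  items, ch) <= 0


class TestSimulation:
    def test_half_probability_rate_within_three_se(self):
        n = 10_000
        items = ItemSet(x_ss=np.full(n, 50.0), t_ss=np.zeros(n),
                        x_ll=np.full(n, 100.0), t_ll=np.full(n, 10.0))
        params = {n_: 0.0 for n_ in get_model("itch").param_names}
        choices = simulate_choices("itch", params, items, 42)
        se = 0.5 / np.sqrt(n)
        assert abs(choices.mean() - 0.5) < 3 * se

    def test_same_seed_identical_draws(self, rng):
        items = random_items(rng, 100)
        a = simulate_choices("hyperbolic", MODEL_PARAMS["hyperbolic"], items, 7)
        b = simulate_choices("hyperbolic", MODEL_PARAMS["hyperbolic"], items, 7)
        np.testing.assert_array_equal(a, b)

    def test_deterministic_limit_all_larger_later(self, factorial_items):
        choices = simulate_choices("hyperbolic", {"k": 1e-6, "sigma": 1e4},
                                   factorial_items, 11)
        assert choices.min() == 1


class TestParameterVector:
    def test_support_violations_rejected(self):
        with pytest.raises(ValueError, match="outside support"):
            ParameterVector("hyperbolic", {"k": -0.1, "sigma": 1.0})
        with pytest.raises(ValueError, match="beta >= delta"):
            ParameterVector("double_exponential",
                            {"beta": 0.01, "delta": 0.5, "omega": 0.5,
                             "sigma": 1.0})
        with pytest.raises(ValueError, match="expected parameters"):
            ParameterVector("exponential", {"k": 0.1})

    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_transform_round_trip(self, model_id):
        model = get_model(model_id)
        theta = np.array([MODEL_PARAMS[model_id][n] for n in model.param_names])
        back = model.from_unconstrained(model.to_unconstrained(theta))
        np.testing.assert_allclose(back, theta, rtol=1e-12)
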