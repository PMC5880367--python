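"""Core latent-class machinery: likelihood, E/M steps, EM fits,
classification, and boundary-adjusted parameter counting."""

import numpy as np
import pytest
from scipy.optimize import minimize

from strategylca import (ModelSpec, Parameters, ResponseData, classify,
                         count_effective_parameters, e_step, fit_em,
                         log_likelihood, m_step)
from conftest import random_small_instance


def _one_subject(pattern, age=36.0):
    return ResponseData(["s1"], np.array([pattern]), [age])


class TestLogLikelihood:
    def test_uniform_bernoulli(self, two_subject_data):
        params = Parameters.from_probs([1.0], np.full((1, 4), 0.5))
        ll = log_likelihood(two_subject_data, ModelSpec(1), params)
        assert ll == pytest.approx(8 * np.log(0.5), abs=1e-12)

    def test_perfect_fit_is_zero(self):
        data = _one_subject([1, 0, 1, 1])
        params = Parameters.from_probs([1.0], [[1.0, 0.0, 1.0, 1.0]])
        assert log_likelihood(data, ModelSpec(1), params) == \
            pytest.approx(0.0, abs=1e-8)

    def test_two_class_mixture_hand_value(self):
        data = _one_subject([1, 1])
        params = Parameters.from_probs([0.5, 0.5],
                                       [[0.9, 0.9], [0.1, 0.1]])
        ll = log_likelihood(data, ModelSpec(2), params)
        assert ll == pytest.approx(np.log(0.41), abs=1e-10)

    def test_dimension_mismatch_raises(self, two_subject_data):
        params = Parameters.from_probs([1.0], [[0.5, 0.5]])
        with pytest.raises(ValueError):
            log_likelihood(two_subject_data, ModelSpec(1), params)

    def test_label_permutation_invariance(self, small_mixture_data):
        data, _ = small_mixture_data
        params = Parameters.from_probs(
            [0.2, 0.5, 0.3],
            [[0.9, 0.8, 0.7, 0.9], [0.1, 0.2, 0.3, 0.1],
             [0.5, 0.5, 0.5, 0.5]])
        base = log_likelihood(data, ModelSpec(3), params)
        for order in ([1, 2, 0], [2, 0, 1], [1, 0, 2]):
            permuted = params.permute_classes(order)
            assert log_likelihood(data, ModelSpec(3), permuted) == \
                pytest.approx(base, abs=1e-10)


class TestEStep:
    def test_single_class_posterior_is_one(self, two_subject_data):
        params = Parameters.from_probs([1.0], np.full((1, 4), 0.5))
        post = e_step(two_subject_data, ModelSpec(1), params)
        assert (post == 1.0).all()

    def test_identical_classes_split_evenly(self, two_subject_data):
        params = Parameters.from_probs([0.5, 0.5],
                                       np.full((2, 4), 0.3))
        post = e_step(two_subject_data, ModelSpec(2), params)
        np.testing.assert_allclose(post, 0.5, atol=1e-12)

    def test_bayes_rule_hand_value(self):
        data = _one_subject([1, 1])
        params = Parameters.from_probs([0.5, 0.5],
                                       [[0.9, 0.9], [0.1, 0.1]])
        post = e_step(data, ModelSpec(2), params)
        np.testing.assert_allclose(post[0], [0.405 / 0.41, 0.005 / 0.41],
                                   atol=1e-9)

    def test_rows_sum_to_one_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            data, K = random_small_instance(rng)
            pi = rng.dirichlet(np.ones(K))
            P = rng.uniform(0.05, 0.95, size=(K, data.n_items))
            post = e_step(data, ModelSpec(K), Parameters.from_probs(pi, P))
            np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)


class TestMStep:
    def test_hard_assignment_gives_column_means(self, two_subject_data):
        post = np.column_stack([np.ones(2), np.zeros(2)])
        params = m_step(two_subject_data, ModelSpec(2), post)
        np.testing.assert_allclose(
            params.response_probs()[0],
            two_subject_data.responses.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(params.class_probs(), [1.0, 0.0],
                                   atol=1e-12)

    def test_weighted_mean_single_item(self):
        data = ResponseData(["a", "b"], np.array([[1], [0]]), [30.0, 40.0])
        post = np.array([[0.8, 0.2], [0.2, 0.8]])
        params = m_step(data, ModelSpec(2), post)
        assert params.response_probs()[0, 0] == pytest.approx(0.8)

    def test_membership_slope_zero_without_age_signal(self):
        rng = np.random.default_rng(3)
        n = 200
        data = ResponseData(np.arange(n),
                            rng.integers(0, 2, size=(n, 3)),
                            rng.uniform(24, 72, n))
        post = np.tile([0.6, 0.4], (n, 1))  # independent of age
        params = m_step(data, ModelSpec(2, "membership"), post)
        assert abs(params.membership_slopes[0]) < 1e-4


class TestFitEM:
    def test_single_class_closed_form(self, two_subject_data):
        fit = fit_em(two_subject_data, ModelSpec(1), n_restarts=3, seed=0)
        np.testing.assert_allclose(
            fit.params.response_probs()[0],
            two_subject_data.responses.mean(axis=0), atol=1e-9)

    def test_matches_direct_optimizer(self):
        """EM optimum agrees with direct numerical maximization of the
        same likelihood on a tiny 2-class instance."""
        rng = np.random.default_rng(5)
        data = ResponseData(np.arange(30),
                            rng.integers(0, 2, size=(30, 3)),
                            rng.uniform(24, 72, 30))
        spec = ModelSpec(2)
        fit = fit_em(data, spec, n_restarts=20, seed=1)

        def negll(theta):
            params = Parameters(theta[:1], np.zeros(1),
                                theta[1:].reshape(2, 3), np.zeros((2, 3)))
            return -log_likelihood(data, spec, params)

        best = np.inf
        for _ in range(15):
            x0 = rng.normal(scale=1.5, size=7)
            res = minimize(negll, x0, method="L-BFGS-B")
            best = min(best, res.fun)
        assert fit.loglik == pytest.approx(-best, abs=1e-4)

    def test_recovers_well_separated_two_class_model(self):
        cfg_probs = np.array([[0.9, 0.9, 0.9, 0.9], [0.1, 0.1, 0.1, 0.1]])
        from strategylca import GeneratorConfig, simulate_dataset
        cfg = GeneratorConfig(response_probs=cfg_probs,
                              class_probs=np.array([0.5, 0.5]),
                              n_per_group=(125, 125, 125, 125), seed=21)
        data, _ = simulate_dataset(cfg)
        fit = fit_em(data, ModelSpec(2), n_restarts=10, seed=2)
        fitted = fit.params.response_probs()
        # align by first item
        if fitted[0, 0] < fitted[1, 0]:
            fitted = fitted[::-1]
        np.testing.assert_allclose(fitted, cfg_probs, atol=0.05)

    def test_response_covariate_recovers_growth_slope(self):
        """A single class whose accuracy grows with age: the fitted
        per-month logit slopes recover the generating 0.06."""
        from strategylca.simulate import accuracy_growth_config
        from strategylca import simulate_dataset
        data, _ = simulate_dataset(accuracy_growth_config(
            seed=17, n_per_group=(500, 500, 500, 500)))
        fit = fit_em(data, ModelSpec(1, "response"), n_restarts=3, seed=1)
        np.testing.assert_allclose(fit.params.response_slopes, 0.06,
                                   atol=0.02)

    def test_reproducible_given_seed(self, small_mixture_data):
        data, _ = small_mixture_data
        a = fit_em(data, ModelSpec(2), n_restarts=4, seed=9)
        b = fit_em(data, ModelSpec(2), n_restarts=4, seed=9)
        assert a.loglik == b.loglik
        np.testing.assert_array_equal(a.posteriors, b.posteriors)

    def test_loglik_history_monotone(self, small_mixture_data):
        data, _ = small_mixture_data
        fit = fit_em(data, ModelSpec(2), n_restarts=1, seed=3)
        assert (np.diff(fit.loglik_history) >= -1e-8).all()

    def test_classes_ordered_by_size(self, small_mixture_data):
        data, _ = small_mixture_data
        fit = fit_em(data, ModelSpec(2), n_restarts=5, seed=4)
        pi = fit.params.class_probs()
        assert pi[0] >= pi[1]

    def test_overparameterized_fit_warns(self):
        data = ResponseData(["a", "b"], np.array([[1, 0], [1, 0]]),
                            [30.0, 40.0])
        with pytest.warns(UserWarning, match="distinct response pattern"):
            fit_em(data, ModelSpec(2), n_restarts=2, seed=0, max_iter=50)


class TestClassify:
    def _with_posteriors(self, post):
        fit = fit_em(_one_subject([1, 1]), ModelSpec(1), n_restarts=1, seed=0)
        fit.posteriors = np.asarray(post, dtype=float)
        return fit

    def test_clear_mode(self):
        fit = self._with_posteriors([[0.9, 0.05, 0.05]])
        assert classify(fit)[0] == 1

    def test_tie_breaks_to_lower_index(self):
        fit = self._with_posteriors([[0.5, 0.5]])
        assert classify(fit)[0] == 1

    def test_boundary_pattern_goes_to_third_class(self, study_truth):
        """Under the study parameters the (0,0,1,1) pattern has zero
        likelihood in classes 1 and 2, so class 3 claims it outright."""
        pi, P = study_truth
        data = _one_subject([0, 0, 1, 1])
        post = e_step(data, ModelSpec(3), Parameters.from_probs(pi, P))
        assert np.argmax(post[0]) + 1 == 3
        assert post[0, 2] == pytest.approx(1.0, abs=1e-6)


class TestEffectiveParameters:
    def _fitted(self, pi, P, spec=None, age_mean=48.0):
        spec = spec or ModelSpec(len(np.atleast_1d(pi)))
        from strategylca.model import FittedModel
        return FittedModel(
            spec=spec, params=Parameters.from_probs(pi, P),
            loglik=-1.0, posteriors=None, n_free_params=0,
            n_boundary_params=0, effective_params=0, converged=True,
            restarts_run=1, best_restart_seed=0, age_mean=age_mean)

    def test_interior_single_class(self):
        nf, nb, eff = count_effective_parameters(
            self._fitted([1.0], [[0.3, 0.4, 0.5, 0.6]]))
        assert (nf, nb, eff) == (4, 0, 4)

    def test_study_probability_matrix_boundary_count(self, study_truth):
        pi, P = study_truth
        nf, nb, eff = count_effective_parameters(self._fitted(pi, P),
                                                 boundary_tol=1e-3)
        assert nf == 14
        assert nb == 8
        assert eff == 6

    def test_empty_class_drops_its_response_row(self):
        nf, nb, eff = count_effective_parameters(
            self._fitted([1.0 - 1e-9, 1e-9],
                         [[0.3, 0.4, 0.5, 0.6], [0.5, 0.5, 0.5, 0.5]]))
        # free: 1 membership + 4 remaining response; boundary: the empty pi
        assert nf == 1 + 4
        assert nb == 1
        assert eff == 4

    def test_boundary_tol_domain(self):
        with pytest.raises(ValueError):
            count_effective_parameters(
                self._fitted([1.0], [[0.5, 0.5, 0.5, 0.5]]),
                boundary_tol=0.5)
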