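"""Weighted loss, gradient descent, closed-form oracle and the estimator."""

import numpy as np
import pytest
from sklearn.base import clone

import fieldray as fr
from fieldray.optimize import (DivergenceError, FitConfig,
                               closed_form_templates, error_summary,
                               fit_templates, training_loss, validation_loss)
from fieldray.templates import TemplateSet, predict_signed_batch, \
    sample_coefficients

from conftest import random_template_set


def _single_bin_setup():
    """n_ids = 1, n_bins = 1 template sets for hand arithmetic."""
    rend = TemplateSet(np.array([5.0]), np.array([[5.0]]), np.array([[5.0]]))
    return rend


class TestTrainingLoss:
    def test_self_consistent_data_gives_zero(self):
        rng = np.random.default_rng(1)
        truth = random_template_set(rng, 2, 8)
        C = sample_coefficients(20, 2, seed=3)
        Y = predict_signed_batch(truth, C, clip=False)
        assert training_loss(truth, truth, C, Y) == pytest.approx(0.0, abs=1e-18)

    def test_prediction_off_by_one_weighs_three_quarters(self):
        rend = _single_bin_setup()
        C = np.array([[0.3]])
        Y = predict_signed_batch(rend, C, clip=False) - 1.0
        assert training_loss(rend, rend, C, Y) == pytest.approx(0.75)

    def test_anchor_plus_prediction_hand_value(self):
        """Generic off by 1 with a c=0 face: L = 0.75*1 + 0.25*1 = 1."""
        rend = _single_bin_setup()
        opt = TemplateSet(np.array([6.0]), np.array([[5.0]]), np.array([[5.0]]))
        C = np.array([[0.0]])
        Y = np.array([[5.0]])  # rendered boundary of the c=0 face
        assert training_loss(opt, rend, C, Y) == pytest.approx(1.0)

    def test_dimension_mismatch_raises(self):
        rend = _single_bin_setup()
        with pytest.raises(ValueError):
            training_loss(rend, rend, np.array([[0.1, 0.2]]), np.array([[5.0]]))


class TestValidationLoss:
    def test_perfect_predictions_are_zero(self):
        rng = np.random.default_rng(4)
        t = random_template_set(rng, 2, 8)
        C = sample_coefficients(7, 2, seed=1)
        Y = predict_signed_batch(t, C, clip=False)
        assert validation_loss(t, C, Y) == pytest.approx(0.0, abs=1e-16)

    def test_one_degree_everywhere_counts_bins(self):
        rng = np.random.default_rng(4)
        t = random_template_set(rng, 2, 16)
        C = sample_coefficients(1, 2, seed=1)
        Y = predict_signed_batch(t, C, clip=False) + 1.0
        assert validation_loss(t, C, Y) == pytest.approx(16.0)

    def test_equals_sum_of_boundary_sq_errors(self):
        rng = np.random.default_rng(8)
        t = random_template_set(rng, 3, 12)
        C = sample_coefficients(9, 3, seed=2)
        Y = predict_signed_batch(t, C, clip=False) + rng.normal(size=(9, 12))
        pred = predict_signed_batch(t, C, clip=False)
        total = sum(fr.boundary_sq_error(pred[j], Y[j]) for j in range(9))
        assert validation_loss(t, C, Y) == pytest.approx(total)


class TestClosedForm:
    def test_no_faces_and_anchor_returns_rendered(self):
        rng = np.random.default_rng(3)
        rend = random_template_set(rng, 2, 8)
        out = closed_form_templates(rend, np.empty((0, 2)), np.empty((0, 8)))
        np.testing.assert_allclose(out.as_vector(), rend.as_vector(), atol=1e-10)

    def test_anchor_only_weights_return_rendered(self):
        rng = np.random.default_rng(3)
        rend = random_template_set(rng, 2, 8)
        C = sample_coefficients(30, 2, seed=5)
        Y = predict_signed_batch(rend, C, clip=False) + 3.0
        cfg = FitConfig(n_total=31, n_validation=1, w_pred=0.0, w_anchor=1.0)
        out = closed_form_templates(rend, C, Y, cfg)
        np.testing.assert_allclose(out.as_vector(), rend.as_vector(), atol=1e-10)

    def test_recovers_generating_templates_when_signs_covered(self):
        rng = np.random.default_rng(6)
        truth = random_template_set(rng, 2, 16)
        rend = TemplateSet(truth.theta_g + rng.normal(0, 1, 16),
                           truth.theta_plus + rng.normal(0, 1, (2, 16)),
                           truth.theta_minus + rng.normal(0, 1, (2, 16)))
        C = sample_coefficients(400, 2, seed=9)  # both signs well covered
        Y = predict_signed_batch(truth, C, clip=False)
        cfg = FitConfig(n_total=401, n_validation=1, w_pred=0.999, w_anchor=0.001)
        out = closed_form_templates(rend, C, Y, cfg)
        assert np.abs(out.theta_g - truth.theta_g).max() < 0.2

    def test_minimality_against_random_perturbations(self):
        rng = np.random.default_rng(12)
        rend = random_template_set(rng, 2, 8)
        C = sample_coefficients(50, 2, seed=13)
        Y = predict_signed_batch(rend, C, clip=False) + rng.normal(size=(50, 8))
        opt = closed_form_templates(rend, C, Y)
        L0 = training_loss(opt, rend, C, Y)
        base = opt.as_vector()
        for _ in range(100):
            pert = TemplateSet.from_vector(base + rng.normal(0, 0.1, base.shape))
            assert training_loss(pert, rend, C, Y) >= L0

    def test_singular_system_is_reported(self):
        rend = _single_bin_setup()
        cfg = FitConfig(n_total=2, n_validation=1, w_pred=1.0, w_anchor=0.0)
        # one face never exercises c < 0: the minus template is unconstrained
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            closed_form_templates(rend, np.array([[0.5]]), np.array([[5.0]]), cfg)

    def test_per_bin_separability(self):
        """Joint solve equals independent per-bin solves."""
        rng = np.random.default_rng(21)
        rend = random_template_set(rng, 2, 6)
        C = sample_coefficients(40, 2, seed=22)
        Y = predict_signed_batch(rend, C, clip=False) + rng.normal(size=(40, 6))
        joint = closed_form_templates(rend, C, Y).as_vector()
        for k in range(6):
            sub = TemplateSet(rend.theta_g[[k]], rend.theta_plus[:, [k]],
                              rend.theta_minus[:, [k]])
            solo = closed_form_templates(sub, C, Y[:, [k]]).as_vector()
            np.testing.assert_allclose(joint[:, [k]], solo, atol=1e-10)


class TestGradientDescent:
    def _instance(self, seed=3, n_faces=50, n_ids=2, n_bins=16):
        rng = np.random.default_rng(seed)
        truth = random_template_set(rng, n_ids, n_bins)
        rend = TemplateSet(
            truth.theta_g + rng.normal(0, 0.5, n_bins),
            truth.theta_plus + rng.normal(0, 0.5, (n_ids, n_bins)),
            truth.theta_minus + rng.normal(0, 0.5, (n_ids, n_bins)))
        C = sample_coefficients(n_faces + 20, n_ids, seed=seed + 1)
        Y = predict_signed_batch(truth, C, clip=False)
        return rend, C[20:], Y[20:], C[:20], Y[:20]

    def test_matches_closed_form_on_small_instance(self):
        rend, C, Y, Cv, Yv = self._instance()
        cfg = FitConfig(n_total=70, n_validation=20, lr=2e-4, patience=50,
                        max_epochs=100_000)
        opt, hist = fit_templates(rend, C, Y, Cv, Yv, cfg)
        exact = closed_form_templates(rend, C, Y, cfg)
        L_gd = training_loss(opt, rend, C, Y, cfg)
        L_ex = training_loss(exact, rend, C, Y, cfg)
        assert L_gd <= L_ex * (1 + 1e-6)

    def test_loss_never_increases_with_small_lr(self):
        rend, C, Y, Cv, Yv = self._instance(seed=10)
        cfg = FitConfig(n_total=70, n_validation=20, lr=5e-5, patience=10,
                        max_epochs=2_000)
        _, hist = fit_templates(rend, C, Y, Cv, Yv, cfg)
        losses = [h.training_loss for h in hist]
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_validation_drop_on_self_consistent_data(self):
        """Perturbed init on exactly-linear data: validation error collapses."""
        rng = np.random.default_rng(5)
        truth = random_template_set(rng, 2, 16)
        C = sample_coefficients(70, 2, seed=6)
        Y = predict_signed_batch(truth, C, clip=False)
        init = TemplateSet(truth.theta_g + rng.normal(0, 1, 16),
                           truth.theta_plus + rng.normal(0, 1, (2, 16)),
                           truth.theta_minus + rng.normal(0, 1, (2, 16)))
        cfg = FitConfig(n_total=70, n_validation=20, lr=2e-4, patience=100,
                        max_epochs=200_000)
        opt, hist = fit_templates(truth, C[20:], Y[20:], C[:20], Y[:20], cfg,
                                  init=init)
        assert hist[-1].validation_loss < 1e-6 * hist[0].validation_loss

    def test_divergence_raises_helpful_error(self):
        rend, C, Y, Cv, Yv = self._instance(seed=2)
        cfg = FitConfig(n_total=70, n_validation=20, lr=10.0, patience=10_000,
                        max_epochs=10_000)
        with pytest.raises(DivergenceError, match="learning rate"):
            fit_templates(rend, C, Y, Cv, Yv, cfg)

    def test_default_learning_rate_is_conservative(self):
        assert FitConfig().lr == 5e-8


class TestFitConfig:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            FitConfig(w_pred=0.9, w_anchor=0.2)

    def test_validation_split_bounds(self):
        with pytest.raises(ValueError):
            FitConfig(n_total=10, n_validation=10)


class TestErrorSummary:
    def test_hand_examples(self):
        s = error_summary([1.0, 2.0, 3.0])
        assert (s["min"], s["mean"], s["median"], s["max"]) == (1, 2, 2, 3)
        s1 = error_summary([7.5])
        assert set(s1.values()) == {7.5}

    def test_even_count_median_is_midpoint(self):
        assert error_summary([1.0, 2.0, 10.0, 20.0])["median"] == 6.0

    def test_against_independent_oracle(self):
        rng = np.random.default_rng(17)
        e = rng.exponential(size=10_000)
        s = error_summary(e)
        srt = np.sort(e)
        assert s["min"] == srt[0] and s["max"] == srt[-1]
        assert s["mean"] == pytest.approx(srt.sum() / len(srt))
        assert s["median"] == pytest.approx((srt[4999] + srt[5000]) / 2)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            error_summary([])


class TestEstimator:
    def test_sklearn_protocol(self):
        est = fr.TemplateBoundaryPredictor(lr=1e-3)
        params = est.get_params()
        assert params["lr"] == 1e-3
        est2 = clone(est).set_params(mode="symmetric")
        assert est2.mode == "symmetric"

    def test_fit_exact_matches_oracle_and_predicts(self):
        rng = np.random.default_rng(31)
        rend = random_template_set(rng, 2, 12)
        C = sample_coefficients(60, 2, seed=32)
        Y = predict_signed_batch(rend, C, clip=False) + rng.normal(size=(60, 12))
        est = fr.TemplateBoundaryPredictor(templates=rend, optimize="exact",
                                           n_validation=10)
        est.fit(C, Y)
        cfg = FitConfig(n_total=60, n_validation=10)
        oracle = closed_form_templates(rend, C[10:], Y[10:], cfg)
        np.testing.assert_allclose(est.templates_.as_vector(),
                                   oracle.as_vector(), atol=1e-10)
        assert est.predict(C).shape == (60, 12)

    def test_unoptimized_predicts_from_given_templates(self):
        rng = np.random.default_rng(33)
        rend = random_template_set(rng, 2, 12)
        C = sample_coefficients(5, 2, seed=34)
        est = fr.TemplateBoundaryPredictor(templates=rend, optimize=None)
        est.fit(C, predict_signed_batch(rend, C))
        np.testing.assert_array_equal(est.predict(C),
                                      predict_signed_batch(rend, C))

    def test_requires_templates(self):
        with pytest.raises(ValueError, match="templates"):
            fr.TemplateBoundaryPredictor().fit(np.zeros((4, 2)), np.zeros((4, 8)))
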