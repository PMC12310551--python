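"""End-to-end experiment drivers on the synthetic head."""

import numpy as np
import pytest

import fieldray as fr
from fieldray import experiments
from fieldray.experiments import (ExperimentConfig, eye_rig,
                                  render_template_set,
                                  run_prediction_experiment,
                                  run_variability_experiment,
                                  template_coefficient_grid, trace_boundary)


class TestCoefficientGrid:
    def test_small_grid_layout(self):
        grid = template_coefficient_grid(3)
        assert grid.shape == (7, 3)
        assert np.all(grid[0] == 0)
        np.testing.assert_array_equal(grid[1], [1, 0, 0])
        np.testing.assert_array_equal(grid[4], [-1, 0, 0])
        # every non-generic row touches exactly one parameter at magnitude 1
        assert np.all(np.abs(grid[1:]).sum(axis=1) == 1)

    def test_full_identity_space_has_201_faces(self):
        assert template_coefficient_grid(100).shape[0] == 201


class TestRenderTemplateSet:
    def test_three_parameter_model_gives_seven_boundaries(
            self, synthetic_templates):
        assert synthetic_templates.n_ids == 3
        assert synthetic_templates.as_vector().shape[0] == 7

    def test_generic_row_is_the_traced_generic_boundary(
            self, synthetic_model, synthetic_rig, small_cfg,
            synthetic_templates):
        mesh = fr.blend_face(synthetic_model, np.zeros(3))
        b = trace_boundary(mesh, synthetic_rig, small_cfg.n_bins)
        np.testing.assert_array_equal(synthetic_templates.theta_g, b.theta)

    def test_features_dent_the_field_locally(self, synthetic_templates):
        """Each morph changes the boundary somewhere but not everywhere."""
        for i in range(3):
            delta = np.abs(synthetic_templates.theta_plus[i]
                           - synthetic_templates.theta_g)
            assert delta.max() > 0.5
            assert (delta < 0.05).sum() > synthetic_templates.n_bins // 4

    def test_cache_serves_rerun_without_retracing(self, synthetic_model,
                                                  tmp_path, monkeypatch):
        cfg = ExperimentConfig(res=48, n_bins=90, n_faces=2, seed=1,
                               out_dir=tmp_path)
        first = render_template_set(synthetic_model, cfg)
        calls = {"n": 0}

        def boom(*a, **k):
            calls["n"] += 1
            raise AssertionError("cache miss")

        monkeypatch.setattr(experiments, "trace_boundary", boom)
        second = render_template_set(synthetic_model, cfg)
        assert calls["n"] == 0
        np.testing.assert_allclose(second.as_vector(), first.as_vector(),
                                   atol=1e-9)


class TestVariability:
    def test_reproducible_and_in_range(self, synthetic_model, tmp_path):
        cfg = ExperimentConfig(res=64, n_bins=120, n_faces=4, seed=3,
                               out_dir=tmp_path / "a")
        r1 = run_variability_experiment(synthetic_model, cfg)
        r2 = run_variability_experiment(
            synthetic_model,
            ExperimentConfig(res=64, n_bins=120, n_faces=4, seed=3,
                             out_dir=tmp_path / "b"))
        np.testing.assert_array_equal(r1["percent_decrease"],
                                      r2["percent_decrease"])
        assert np.all((r1["percent_decrease"] >= 0)
                      & (r1["percent_decrease"] <= 100))
        assert (tmp_path / "a" / "variability.csv").exists()
        assert r1["metadata"]["seed"] == 3

    def test_summary_is_the_error_summary_of_percents(self, synthetic_model,
                                                      tmp_path):
        cfg = ExperimentConfig(res=48, n_bins=90, n_faces=3, seed=5,
                               out_dir=tmp_path)
        r = run_variability_experiment(synthetic_model, cfg)
        s = fr.error_summary(r["percent_decrease"])
        assert r["summary"] == s


class TestPredictionExperiment:
    def test_errors_and_key_faces(self, synthetic_model, tmp_path):
        cfg = ExperimentConfig(res=64, n_bins=120, n_faces=6, seed=2,
                               out_dir=tmp_path)
        r = run_prediction_experiment(synthetic_model, cfg)
        e = r["errors"]
        assert len(e) == 6
        assert r["summary"] == fr.error_summary(e)
        assert e[r["key_faces"]["best"]] == e.min()
        assert e[r["key_faces"]["worst"]] == e.max()
        assert e[r["key_faces"]["best"]] <= e[r["key_faces"]["median"]] \
            <= e[r["key_faces"]["worst"]]

    def test_linear_model_beats_generic_baseline(self, synthetic_model,
                                                 synthetic_templates,
                                                 synthetic_rig, small_cfg):
        """Template predictions explain real shape-driven boundary changes."""
        coeffs = fr.sample_coefficients(5, 3, seed=11)
        pred = fr.templates.predict_signed_batch(synthetic_templates, coeffs)
        err_model = err_base = 0.0
        for c, p in zip(coeffs, pred):
            b = trace_boundary(fr.blend_face(synthetic_model, c),
                               synthetic_rig, small_cfg.n_bins).theta
            err_model += fr.boundary_sq_error(p, b)
            err_base += fr.boundary_sq_error(synthetic_templates.theta_g, b)
        assert err_model < err_base
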