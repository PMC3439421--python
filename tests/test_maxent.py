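"""Feature construction, the Gibbs fit, projection and the logistic output."""

import math

import numpy as np
import pandas as pd
import pytest

from sdmsense import (
    EnvStack,
    FeatureBasis,
    GridSpec,
    MaxentModel,
    build_features,
    fit_maxent,
    max_probability,
    project,
)
from sdmsense.exceptions import FitError, ProjectionError
from sdmsense.maxent import design_matrix, maxent_objective


def _fit_simple(pres, bg, **kw):
    feats = [FeatureBasis("linear", "env1", 0.0, 1.0)]
    return fit_maxent(pd.DataFrame({"env1": pres}), pd.DataFrame({"env1": bg}),
                      feats, **kw)


class TestBuildFeatures:
    def test_linear_only_gives_one_feature_per_covariate(self, stack10):
        feats = build_features(stack10, use_quadratic=False, use_hinge=False)
        assert [f.kind for f in feats] == ["linear", "linear"]

    def test_full_basis_count(self, stack10):
        feats = build_features(stack10, hinge_knots=5)
        # per covariate: 1 linear + 1 quadratic + 2*5 hinge
        assert len(feats) == 2 * (1 + 1 + 10)
        hinges = [f for f in feats if f.kind == "hinge"]
        assert all(f.scale_min < f.knot < f.scale_max for f in hinges)

    def test_constant_covariate_yields_degenerate_features(self, grid10):
        stack = EnvStack(grid10, ["flat"], np.zeros((1, 10, 10)),
                         np.ones((10, 10), bool))
        feats = build_features(stack, use_hinge=False)
        assert feats and all(f.is_degenerate for f in feats)
        with pytest.raises(FitError):
            fit_maxent(pd.DataFrame({"flat": [0.0]}),
                       pd.DataFrame({"flat": [0.0, 0.0]}), feats)

    def test_features_rescale_background_range_to_unit_interval(self, stack10):
        feats = build_features(stack10, use_quadratic=False, use_hinge=False)
        table = stack10.valid_table()
        X = design_matrix(feats, table)
        assert X.min() == pytest.approx(0.0) and X.max() == pytest.approx(1.0)


class TestFitMaxent:
    def test_no_signal_gives_zero_weights_and_uniform_density(self, stack10):
        feats = build_features(stack10, hinge_knots=3)
        table = stack10.valid_table()
        model = fit_maxent(table, table, feats, reg_multiplier=1.0)
        assert np.all(model.weights == 0.0)
        assert model.converged
        assert model.entropy == pytest.approx(math.log(100), abs=1e-9)
        q = model.raw_density(table)
        np.testing.assert_allclose(q, 1.0 / 100, rtol=1e-12)

    def test_objective_equals_analytic_gibbs_loglik(self):
        # 100-cell toy grid, linear feature, lambda held fixed
        rng = np.random.default_rng(0)
        z_bg = rng.random(100)
        z_pr = rng.random(17)
        lam = np.array([1.37])
        feats = [FeatureBasis("linear", "env1", 0.0, 1.0)]
        X_pr = design_matrix(feats, pd.DataFrame({"env1": z_pr}))
        X_bg = design_matrix(feats, pd.DataFrame({"env1": z_bg}))
        got = maxent_objective(lam, X_pr, X_bg, np.zeros(1))
        # independent oracle in plain python floats
        log_z = math.log(sum(math.exp(lam[0] * z) for z in z_bg))
        want = -sum(lam[0] * z for z in z_pr) / len(z_pr) + log_z
        assert got == pytest.approx(want, abs=1e-9)

    def test_recovers_known_gibbs_weight(self):
        # presences simulated from q(x) ∝ exp(2·f(x)); brute-force likelihood
        # grid is the oracle for the optimizer
        rng = np.random.default_rng(42)
        z_bg = rng.random(100)
        lam_true = 2.0
        q = np.exp(lam_true * z_bg)
        q /= q.sum()
        draws = rng.choice(100, size=2000, p=q)
        model = _fit_simple(z_bg[draws], z_bg, reg_multiplier=0.0)
        lam_hat = model.weights[0]
        feats = [FeatureBasis("linear", "env1", 0.0, 1.0)]
        X_pr = design_matrix(feats, pd.DataFrame({"env1": z_bg[draws]}))
        X_bg = design_matrix(feats, pd.DataFrame({"env1": z_bg}))
        grid_l = np.arange(0.0, 4.0, 1e-3)
        objs = [maxent_objective(np.array([l]), X_pr, X_bg, np.zeros(1)) for l in grid_l]
        lam_grid = grid_l[int(np.argmin(objs))]
        assert lam_hat == pytest.approx(lam_grid, abs=5e-3)
        assert abs(lam_hat - lam_true) <= 0.1 * lam_true

    def test_raw_density_sums_to_one_over_background(self, stack10):
        feats = build_features(stack10, hinge_knots=4)
        bg = stack10.valid_table()
        rng = np.random.default_rng(3)
        pres = bg.iloc[rng.choice(len(bg), 40)]
        for reg in (0.5, 1.0):
            model = fit_maxent(pres, bg, feats, reg_multiplier=reg)
            assert abs(model.raw_density(bg).sum() - 1.0) < 1e-6

    def test_l1_norm_nonincreasing_in_regularization(self, stack10):
        feats = build_features(stack10, hinge_knots=4)
        bg = stack10.valid_table()
        rng = np.random.default_rng(4)
        weights = np.exp(2.0 * bg["env1"].to_numpy())
        pres = bg.iloc[rng.choice(len(bg), 200, p=weights / weights.sum())]
        norms = []
        for reg in (0.5, 1.0, 2.0):
            model = fit_maxent(pres, bg, feats, reg_multiplier=reg)
            norms.append(np.abs(model.weights).sum())
        assert norms[0] >= norms[1] >= norms[2]

    def test_complete_separation_stays_finite_under_l1(self):
        bg = np.linspace(0, 1, 50)
        model = _fit_simple(np.ones(20), bg, reg_multiplier=1.0)
        assert np.all(np.isfinite(model.weights))
        assert model.converged


class TestProjection:
    def _model(self, stack, seed=0, **kw):
        feats = build_features(stack, hinge_knots=4)
        bg = stack.valid_table()
        rng = np.random.default_rng(seed)
        weights = np.exp(1.5 * bg["env1"].to_numpy())
        pres = bg.iloc[rng.choice(len(bg), 60, p=weights / weights.sum())]
        return fit_maxent(pres, bg, feats, **kw)

    def test_projection_is_reproducible_bit_for_bit(self, stack10):
        model = self._model(stack10)
        s1 = project(model, stack10)
        s2 = project(model, stack10)
        np.testing.assert_array_equal(s1.probability, s2.probability)

    def test_training_surface_matches_fit_internals(self, stack10):
        model = self._model(stack10)
        surface = project(model, stack10, clamp=True)
        table = stack10.valid_table()
        q = np.exp(model.linear_score(table) - model.log_normalizer)
        expected = model.logistic_from_raw(q)
        got = surface.probability[table["row"], table["col"]]
        np.testing.assert_array_equal(got, expected)

    def test_zero_model_projects_constant_prevalence(self, stack10):
        table = stack10.valid_table()
        feats = build_features(stack10, hinge_knots=3)
        model = fit_maxent(table, table, feats)  # no signal → all weights zero
        surface = project(model, stack10)
        vals = surface.probability[surface.valid_mask]
        # q = 1/n, H = log n, so p = tau/(1+tau) = 1/3 everywhere
        np.testing.assert_allclose(vals, 1.0 / 3.0, rtol=1e-12)

    def test_clamping_flags_exactly_the_out_of_range_cells(self, stack10):
        model = self._model(stack10)
        shifted = EnvStack(
            grid=stack10.grid,
            layer_names=stack10.layer_names,
            values=stack10.values + np.array([0.6, 0.0])[:, None, None],
            valid_mask=stack10.valid_mask,
        )
        surface = project(model, shifted, clamp=True)
        lo, hi = model.covariate_ranges()["env1"]
        expected = shifted.values[0] > hi
        np.testing.assert_array_equal(surface.clamped_mask, expected)

    def test_missing_layer_is_a_projection_error(self, stack10, grid10):
        model = self._model(stack10)
        partial = EnvStack(grid10, ["env1"], stack10.values[:1], stack10.valid_mask)
        with pytest.raises(ProjectionError, match="env2"):
            project(model, partial)

    def test_logistic_preserves_cell_ranking(self, stack10):
        model = self._model(stack10)
        table = stack10.valid_table()
        q = model.raw_density(table)
        p = project(model, stack10).probability[table["row"], table["col"]]
        np.testing.assert_array_equal(np.argsort(q, kind="stable"),
                                      np.argsort(p, kind="stable"))

    def test_max_probability_equals_exhaustive_scan(self, stack10):
        model = self._model(stack10)
        surface = project(model, stack10)
        brute = max(
            surface.probability[r, c]
            for r in range(10)
            for c in range(10)
            if surface.valid_mask[r, c]
        )
        assert max_probability(surface) == brute == surface.max_probability


class TestSerialization:
    def test_roundtrip_is_bit_exact(self, tmp_path, stack10):
        feats = build_features(stack10, hinge_knots=4)
        bg = stack10.valid_table()
        rng = np.random.default_rng(9)
        weights = np.exp(1.2 * bg["env2"].to_numpy())
        pres = bg.iloc[rng.choice(len(bg), 50, p=weights / weights.sum())]
        model = fit_maxent(pres, bg, feats)
        path = tmp_path / "model.json"
        model.save(path)
        back = MaxentModel.load(path)
        np.testing.assert_array_equal(model.weights, back.weights)
        np.testing.assert_array_equal(model.reg_weights, back.reg_weights)
        assert (model.entropy, model.log_normalizer, model.tau) == (
            back.entropy, back.log_normalizer, back.tau)
        s1 = project(model, stack10)
        s2 = project(back, stack10)
        np.testing.assert_array_equal(s1.probability, s2.probability)
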