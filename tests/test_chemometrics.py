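"""MCR-ALS, PLS, and epsilon-SVR engine behaviour."""

import numpy as np
import pytest

from sorsq.chemometrics import (
    SpectralMatrix,
    evaluate,
    fit_pls,
    fit_svr,
    load_model,
    match_components,
    mcr_als,
    save_model,
    venetian_blinds,
)
from sorsq.spectra import WavenumberGrid


def _lorentz(nu, center, fwhm):
    g = fwhm / 2
    return g * g / ((nu - center) ** 2 + g * g)


@pytest.fixture(scope="module")
def small_grid():
    return WavenumberGrid(200, 1800, 401)


class TestVenetianBlinds:
    def test_study_layout_n78_39_splits(self):
        """The training-set split: sample i -> fold (i mod 39), every fold
        holding exactly two samples."""
        folds = venetian_blinds(78, 39, 1)
        np.testing.assert_array_equal(folds, np.arange(78) % 39)
        counts = np.bincount(folds)
        assert counts.size == 39 and np.all(counts == 2)

    def test_thickness_groups_adjacent_samples(self):
        folds = venetian_blinds(12, 3, 2)
        np.testing.assert_array_equal(folds, [0, 0, 1, 1, 2, 2, 0, 0, 1, 1, 2, 2])


class TestMcrAls:
    def test_two_component_generate_and_recover(self, small_grid):
        nu = small_grid.values
        S_true = np.vstack([
            _lorentz(nu, 800, 30) + 0.4 * _lorentz(nu, 1200, 40),
            _lorentz(nu, 1500, 35) + 0.3 * _lorentz(nu, 600, 25),
        ])
        rng = np.random.default_rng(0)
        C_true = rng.random((30, 2))
        X = C_true @ S_true
        model = mcr_als(X, k=2, max_iter=500, tol=1e-12)
        matches = match_components(model.S, {"a": S_true[0], "b": S_true[1]})
        assert {name for name, _ in matches} == {"a", "b"}
        for _, cos in matches:
            assert cos >= 0.99
        assert model.cumulative_fit >= 99.9

    def test_rank_one_data_fits_with_single_component(self, small_grid):
        nu = small_grid.values
        row = _lorentz(nu, 1000, 30)
        X = np.tile(row, (8, 1))
        model = mcr_als(X, k=1)
        assert model.cumulative_fit >= 99.9

    def test_objective_monotone_nonincreasing(self, small_grid):
        rng = np.random.default_rng(3)
        nu = small_grid.values
        S = np.vstack([_lorentz(nu, c, 30) for c in (700, 1000, 1400)])
        X = rng.random((25, 3)) @ S + 0.01 * rng.random((25, nu.size))
        model = mcr_als(X, k=3, max_iter=100)
        hist = np.array(model.objective_history)
        assert np.all(np.diff(hist) <= 1e-9 * hist[0])

    def test_per_component_fits_partition_cumulative(self, small_grid):
        rng = np.random.default_rng(4)
        nu = small_grid.values
        S = np.vstack([_lorentz(nu, c, 30) for c in (800, 1300)])
        X = rng.random((20, 2)) @ S
        model = mcr_als(X, k=2)
        assert model.per_component_fit.sum() == pytest.approx(model.cumulative_fit, abs=1e-6)
        assert np.all(np.diff(model.per_component_fit) <= 0)  # sorted descending

    def test_invalid_k_rejected(self, small_grid):
        X = np.ones((5, len(small_grid)))
        with pytest.raises(ValueError):
            mcr_als(X, k=6)


class TestPls:
    def test_exact_linear_system_fits_with_near_zero_residual(self):
        rng = np.random.default_rng(1)
        X = rng.random((40, 10))
        b = rng.random((10, 2))
        Y = X @ b
        # n_lv equal to the rank of X: the linear map is exactly identifiable
        model = fit_pls(X, Y, n_lv=10, cv_splits=10, targets=["y0", "y1"])
        pred = model.predict(X)
        assert np.max(np.abs(pred - Y)) < 1e-8 * np.max(np.abs(Y))
        assert np.all(model.cv_rmse < 1e-6 * np.abs(Y).max())

    def test_captured_variance_monotone_in_n_lv(self):
        rng = np.random.default_rng(2)
        X = rng.random((30, 50))
        Y = rng.random((30, 1))
        fits = [
            fit_pls(X, Y, n_lv=k, compute_cv=False).x_variance[-1]
            for k in (1, 2, 4, 8)
        ]
        assert np.all(np.diff(fits) >= -1e-12)
        # within one model the per-LV cumulative curve is non-decreasing too
        model = fit_pls(X, Y, n_lv=8, compute_cv=False)
        assert np.all(np.diff(model.x_variance) >= -1e-12)

    def test_n_lv_exceeding_rank_rejected(self):
        rng = np.random.default_rng(3)
        base = rng.random((3, 30))
        X = np.vstack([base] * 5)  # rank <= 3
        Y = rng.random((15, 1))
        with pytest.raises(ValueError):
            fit_pls(X, Y, n_lv=10, compute_cv=False)

    def test_diagnostics_present_with_limits(self):
        rng = np.random.default_rng(4)
        X = rng.random((30, 40))
        Y = rng.random((30, 2))
        model = fit_pls(X, Y, n_lv=4, cv_splits=10)
        assert model.q_residuals.shape == (30,)
        assert model.hotelling_t2.shape == (30,)
        assert model.q_limit > 0 and model.t2_limit > 0


class TestSvr:
    def test_point_inside_tube_predicted_within_epsilon(self):
        rng = np.random.default_rng(5)
        X = rng.random((30, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        model = fit_svr(X, y[:, None], c_grid=[100.0], gamma_grid=[0.1],
                        epsilon=0.5, cv_splits=10, targets=["y"])
        pred = model.predict(X)[:, 0]
        # all training residuals bounded by the epsilon tube (+ slack for the
        # few support vectors outside)
        assert np.median(np.abs(pred - y)) <= 0.5 + 1e-6

    def test_constant_response_predicts_constant(self):
        rng = np.random.default_rng(6)
        X = rng.random((20, 8))
        y = np.full(20, 42.0)
        model = fit_svr(X, y[:, None], c_grid=[10.0], gamma_grid=[0.01],
                        cv_splits=10, targets=["y"])
        pred = model.predict(rng.random((10, 8)))
        np.testing.assert_allclose(pred, 42.0, atol=0.5 + 1e-9)
        est = model.estimators["y"]
        assert est.dual_coef_.size == 0 or np.allclose(est.dual_coef_, 0.0)

    def test_sine_toy_within_2x_of_kernel_ridge_oracle(self):
        """1-D y=sin(x): grid-searched RBF SVR against a brute-force kernel
        ridge solution as an independent alternative estimator."""
        rng = np.random.default_rng(7)
        x = np.linspace(0, 2 * np.pi, 20)[:, None]
        y = np.sin(x[:, 0])
        x_test = rng.uniform(0, 2 * np.pi, 50)[:, None]
        y_test = np.sin(x_test[:, 0])

        gamma = 1.0
        K = np.exp(-gamma * (x - x.T) ** 2)
        alpha = np.linalg.solve(K + 1e-2 * np.eye(20), y)
        Kt = np.exp(-gamma * (x_test - x.T) ** 2)
        ridge_rmse = np.sqrt(np.mean((Kt @ alpha - y_test) ** 2))

        model = fit_svr(x, y[:, None], epsilon=0.005, cv_splits=10, targets=["y"])
        svr_rmse = np.sqrt(np.mean((model.predict(x_test)[:, 0] - y_test) ** 2))
        assert svr_rmse <= 2.0 * ridge_rmse + 1e-3

    def test_duplicating_inside_tube_sample_leaves_prediction_unchanged(self):
        rng = np.random.default_rng(8)
        X = rng.random((25, 6))
        y = X @ np.arange(1.0, 7.0)
        model1 = fit_svr(X, y[:, None], c_grid=[100.0], gamma_grid=[0.1],
                         cv_splits=5, targets=["y"])
        pred1 = model1.predict(X)[:, 0]
        inside = np.abs(pred1 - y) < 0.25  # strictly inside the 0.5 tube
        i = int(np.flatnonzero(inside)[0])
        X2 = np.vstack([X, X[i]])
        y2 = np.append(y, y[i])
        model2 = fit_svr(X2, y2[:, None], c_grid=[100.0], gamma_grid=[0.1],
                         cv_splits=5, targets=["y"])
        probe = rng.random((20, 6))
        np.testing.assert_allclose(model1.predict(probe), model2.predict(probe), atol=0.05)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            fit_svr(np.ones((5, 2)), np.ones(5), c_grid=[], gamma_grid=[1.0])

    def test_tie_break_prefers_smaller_c_and_gamma(self):
        # constant y: every grid point attains identical CV RMSE
        X = np.linspace(0, 1, 12)[:, None]
        y = np.full(12, 5.0)
        model = fit_svr(X, y[:, None], c_grid=[1.0, 10.0, 100.0],
                        gamma_grid=[0.01, 0.1, 1.0], cv_splits=4, targets=["y"])
        hp = model.hyperparams["y"]
        assert hp.C_cost == 1.0 and hp.gamma == 0.01


class TestEvaluate:
    def test_perfect_predictions(self):
        class Identity:
            targets = ["a", "b"]

            def predict(self, X):
                return X

        Y = np.random.default_rng(0).random((10, 2))
        rep = evaluate(Identity(), Y, Y)
        np.testing.assert_allclose(rep.rmse, 0.0)
        np.testing.assert_allclose(rep.r2, 1.0)

    def test_constant_mean_predictor_gives_zero_r2(self):
        rng = np.random.default_rng(1)
        Y = rng.random((50, 1))

        class MeanModel:
            targets = ["y"]

            def predict(self, X):
                return np.full((X.shape[0], 1), Y.mean())

        rep = evaluate(MeanModel(), np.zeros((50, 3)), Y)
        assert rep.r2[0] == pytest.approx(0.0, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        class Identity:
            targets = ["a"]

            def predict(self, X):
                return X

        with pytest.raises(ValueError):
            evaluate(Identity(), np.ones((5, 2)), np.ones((5, 3)))


class TestPersistence:
    def test_svr_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        X = rng.random((30, 10))
        Y = np.column_stack([X @ rng.random(10), X @ rng.random(10)])
        model = fit_svr(X, Y, c_grid=[100.0], gamma_grid=[0.1], cv_splits=5,
                        targets=["u", "v"])
        path = tmp_path / "m.json"
        save_model(model, path)
        loaded = load_model(path)
        probe = rng.random((7, 10))
        np.testing.assert_allclose(loaded.predict(probe), model.predict(probe), atol=1e-9)

    def test_pls_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        X = rng.random((30, 12))
        Y = (X @ rng.random((12, 2)))
        model = fit_pls(X, Y, n_lv=5, compute_cv=False, targets=["u", "v"])
        path = tmp_path / "m.json"
        save_model(model, path)
        loaded = load_model(path)
        probe = rng.random((6, 12))
        np.testing.assert_allclose(loaded.predict(probe), model.predict(probe), atol=1e-9)
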