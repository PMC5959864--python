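"""Calibration models: PLS fit/selection, SVR grid search, RF optimization,
and the train/predict contract."""

import numpy as np
import pandas as pd
import pytest

from withervision import models as M
from withervision.features import FEATURE_NAMES
from withervision.prep import pca_apply, pca_fit, zscore_apply, zscore_fit
from withervision.simulate import WitheringDesign, simulate_feature_table


def nipals_pls1(X, y, npc):
    """Independent reference PLS1: classic NIPALS deflation, used only as a
    test oracle."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    xm, ym = X.mean(axis=0), y.mean()
    E, f = X - xm, y - ym
    W, P, Q = [], [], []
    for _ in range(npc):
        w = E.T @ f
        w /= np.linalg.norm(w)
        t = E @ w
        tt = t @ t
        p = E.T @ t / tt
        q = (f @ t) / tt
        E = E - np.outer(t, p)
        f = f - q * t
        W.append(w), P.append(p), Q.append(q)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    B = W @ np.linalg.solve(P.T @ W, Q)

    def predict(Xnew):
        return (np.asarray(Xnew, float) - xm) @ B + ym

    return predict


@pytest.fixture(scope="module")
def latent_data():
    """y linear in 3 latent factors spread over 15 observed variables."""
    rng = np.random.default_rng(8)
    n = 60
    T = rng.normal(size=(n, 3))
    P = rng.normal(size=(3, 15))
    X = T @ P
    y = T @ np.array([1.0, -0.5, 0.25])
    return X, y


class TestPLS:
    def test_rank_one_single_factor_is_exact(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=40)
        X = np.outer(t, rng.normal(size=8))
        y = 2.0 * t + 1.0
        model = M.fit_pls(X, y, 1)
        assert np.sqrt(np.mean((model.predict(X) - y) ** 2)) < 1e-8

    @pytest.mark.parametrize("npc", [1, 2, 3])
    def test_matches_independent_nipals_oracle(self, latent_data, npc):
        X, y = latent_data
        Xn = X + np.random.default_rng(1).normal(0, 0.1, X.shape)
        model = M.fit_pls(Xn, y, npc)
        oracle = nipals_pls1(Xn, y, npc)
        np.testing.assert_allclose(model.predict(Xn), oracle(Xn), atol=1e-6)

    def test_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        model = M.fit_pls(X, y, 5)
        Xc = np.column_stack([np.ones(30), X])
        beta = np.linalg.lstsq(Xc, y, rcond=None)[0]
        np.testing.assert_allclose(model.predict(X), Xc @ beta, atol=1e-6)

    def test_score_orthogonality(self, latent_data):
        X, y = latent_data
        model = M.fit_pls(X, y, 3)
        G = model.x_scores.T @ model.x_scores
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)

    def test_npc_too_large_rejected(self, latent_data):
        X, y = latent_data
        with pytest.raises(ValueError, match="npc"):
            M.fit_pls(X, y, 16)


class TestSelectNpc:
    def test_recovers_latent_dimension(self, latent_data):
        X, y = latent_data
        best, curve = M.select_npc(X, y, npc_range=range(1, 11),
                                   criterion="rmsecv", folds=5, seed=0)
        assert best in (3, 4)
        assert list(curve.columns) == ["npc", "error"]

    def test_rank_one_noiseless(self):
        rng = np.random.default_rng(3)
        t = rng.normal(size=50)
        X = np.outer(t, rng.normal(size=10))
        y = t.copy()
        best, _ = M.select_npc(X, y, npc_range=range(1, 6), folds=5, seed=0)
        assert best == 1

    def test_rmsec_curve_non_increasing(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 10))
        y = X @ rng.normal(size=10) + rng.normal(0, 0.5, 50)
        _, curve = M.select_npc(X, y, npc_range=range(1, 11), criterion="rmsec")
        assert (np.diff(curve["error"].to_numpy()) <= 1e-12).all()

    def test_too_few_samples_for_folds_rejected(self):
        X = np.eye(5)
        y = np.arange(5.0)
        with pytest.raises(ValueError, match="fold"):
            M.select_npc(X, y, npc_range=[1], folds=10)


class TestSVR:
    def test_spec_validation(self):
        with pytest.raises(ValueError, match="kernel"):
            M.SVRSpec(kernel="laplacian")
        with pytest.raises(ValueError, match="positive"):
            M.SVRSpec(c=-1.0)

    def test_constant_y_predicts_within_epsilon(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        y = np.full(20, 0.5)
        model = M.fit_svr(X, y, M.SVRSpec(epsilon=0.01))
        assert np.abs(model.predict(X) - 0.5).max() <= 0.01 + 1e-9

    def test_linear_kernel_realizable_tube(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        y = X @ np.array([0.2, -0.1, 0.05]) + 0.4
        spec = M.SVRSpec(kernel="linear", c=1e4, g=1.0, epsilon=0.01)
        model = M.fit_svr(X, y, spec)
        rmse = np.sqrt(np.mean((model.predict(X) - y) ** 2))
        assert rmse <= spec.epsilon

    def test_single_point_grid_returned(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        spec, surface = M.grid_search_svr(X, y, c_grid=[2.0], g_grid=[0.5],
                                          folds=3)
        assert spec.c == 2.0 and spec.g == 0.5
        assert len(surface) == 1

    def test_winner_attains_surface_minimum(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 4))
        y = X[:, 0] ** 2 + rng.normal(0, 0.1, 40)
        spec, surface = M.grid_search_svr(
            X, y, c_grid=2.0 ** np.arange(-2, 5), g_grid=2.0 ** np.arange(-4, 3),
            folds=4,
        )
        winner = surface[(surface.c == spec.c) & (surface.g == spec.g)]
        assert winner["rmse"].iloc[0] == surface["rmse"].min()

    def test_constant_y_grid_rejected(self):
        X = np.eye(10)
        with pytest.raises(ValueError, match="constant"):
            M.grid_search_svr(X, np.ones(10))

    def test_rbf_beats_pls_on_quadratic_response(self):
        """Nonlinear-beats-linear ordering on a saturating/quadratic link."""
        rng = np.random.default_rng(9)
        X = rng.normal(size=(80, 5))
        y = X[:, 0] ** 2 + 0.3 * X[:, 1] + rng.normal(0, 0.05, 80)
        spec, surface = M.grid_search_svr(
            X, y, c_grid=2.0 ** np.arange(-4, 9), g_grid=2.0 ** np.arange(-8, 3),
            folds=5, seed=0,
        )
        svr_cv = surface["rmse"].min()
        from sklearn.model_selection import KFold

        kf = KFold(5, shuffle=True, random_state=0)
        preds = np.empty_like(y)
        for tr, te in kf.split(X):
            preds[te] = M.fit_pls(X[tr], y[tr], 5).predict(X[te])
        pls_cv = np.sqrt(np.mean((preds - y) ** 2))
        assert svr_cv <= pls_cv

    def test_fit_reproducible(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        a = M.fit_svr(X, y, M.SVRSpec()).predict(X)
        b = M.fit_svr(X, y, M.SVRSpec()).predict(X)
        np.testing.assert_array_equal(a, b)


class TestRF:
    def test_grid_shape_and_winner_consistency(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 6))
        y = X[:, 0] + rng.normal(0, 0.1, 60)
        spec, grid = M.optimize_rf(X, y, pc_range=range(1, 4),
                                   n_range=range(50, 151, 50), seed=1)
        assert len(grid) == 9
        winner = grid[(grid.pcs == spec.n_input_pcs) & (grid.n_trees == spec.n_trees)]
        assert winner["error"].iloc[0] == grid["error"].min()

    def test_low_dimensional_signal_prefers_few_pcs(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 10))
        y = np.sin(X[:, 0])  # depends on PC1 only, noiseless
        spec, _ = M.optimize_rf(X, y, pc_range=range(1, 11),
                                n_range=[100], criterion="oob", seed=0)
        assert spec.n_input_pcs <= 3

    def test_default_grid_has_200_cells(self):
        """Default protocol: 10 PC choices x 20 forest sizes = 200 cells."""
        import inspect

        sig = inspect.signature(M.optimize_rf)
        pcs = list(sig.parameters["pc_range"].default)
        ns = list(sig.parameters["n_range"].default)
        assert len(pcs) * len(ns) == 200
        assert pcs == list(range(1, 11)) and ns == list(range(50, 1001, 50))
        # the grid frame really enumerates every cell of a requested range
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 10))
        _, grid = M.optimize_rf(X, rng.normal(size=40), pc_range=range(1, 6),
                                n_range=range(50, 201, 50),
                                criterion="rmsec", seed=0)
        assert len(grid) == 20

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        a = M.fit_rf(X, y, M.RFSpec(n_trees=50, n_input_pcs=4, seed=3)).predict(X)
        b = M.fit_rf(X, y, M.RFSpec(n_trees=50, n_input_pcs=4, seed=3)).predict(X)
        np.testing.assert_array_equal(a, b)


@pytest.fixture(scope="module")
def fitted():
    table = simulate_feature_table(WitheringDesign(seed=4))
    std = zscore_fit(table)
    proj = pca_fit(zscore_apply(std, table), n_components=10)
    X = pca_apply(proj, zscore_apply(std, table))
    y = table["moisture"].to_numpy()
    reg = M.fit_svr(X, y, M.SVRSpec(c=1.0, g=0.1))
    model = M.FittedModel(family="svr", regressor=reg, standardizer=std,
                          pca=proj, n_input_pcs=10,
                          spec={"kernel": "rbf", "c": 1.0, "g": 0.1,
                                "epsilon": 0.01})
    return model, table, X, y


class TestFittedModelContract:
    def test_predict_reproduces_in_sample_values(self, fitted):
        model, table, X, y = fitted
        np.testing.assert_allclose(M.predict(model, table),
                                   model.regressor.predict(X), atol=1e-12)

    def test_column_reordering_is_harmless(self, fitted):
        model, table, *_ = fitted
        shuffled = table[list(table.columns[::-1])]
        np.testing.assert_allclose(M.predict(model, shuffled),
                                   M.predict(model, table), atol=1e-12)

    def test_missing_column_named_in_error(self, fitted):
        model, table, *_ = fitted
        broken = table.rename(columns={"L_star": "lightness"})
        with pytest.raises(ValueError, match="L_star"):
            M.predict(model, broken)

    def test_save_load_roundtrip(self, fitted, tmp_path):
        model, table, *_ = fitted
        M.save_model(model, tmp_path / "bundle")
        loaded = M.load_model(tmp_path / "bundle")
        np.testing.assert_allclose(M.predict(loaded, table),
                                   M.predict(model, table), atol=1e-12)
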