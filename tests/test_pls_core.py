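"""NIPALS PLS estimator: algebraic invariants, prediction, Hotelling region."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone

import agropls as ag
from agropls.pls_core import (
    PLSRegressionNIPALS,
    center_scale,
    hotelling_ellipse,
    nipals_pls,
    r2y,
)


def _random_problem(rng, n=20, p=8, m=3):
    X = rng.normal(size=(n, p))
    B = rng.normal(size=(p, m))
    Y = X @ B + 0.5 * rng.normal(size=(n, m))
    return X, Y


class TestCenterScale:
    def test_columns_become_standardized(self, rng):
        X, Y = _random_problem(rng)
        Xs, Ys, pp = center_scale(X, Y)
        for M in (Xs, Ys):
            assert np.allclose(M.mean(axis=0), 0.0, atol=1e-12)
            assert np.allclose(M.std(axis=0, ddof=1), 1.0, atol=1e-12)
        assert np.allclose(pp.inverse_y(Ys), Y, atol=1e-12)

    def test_scale_y_false_only_centres(self, rng):
        X, Y = _random_problem(rng)
        _, Ys, _ = center_scale(X, Y, scale_y=False)
        assert np.allclose(Ys.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Ys, Y - Y.mean(axis=0), atol=1e-12)

    def test_constant_column_named_in_error(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "flat", "c"])
        X["flat"] = 7.0
        with pytest.raises(ValueError, match="flat"):
            center_scale(X, rng.normal(size=10))


class TestFittedModel:
    @pytest.fixture()
    def fitted(self, rng):
        X, Y = _random_problem(rng)
        return PLSRegressionNIPALS(n_components=3).fit(X, Y), X, Y

    def test_shapes_and_unit_weights(self, fitted):
        model, X, Y = fitted
        n, p = X.shape
        m = Y.shape[1]
        assert model.x_weights_.shape == (p, 3)
        assert model.x_loadings_.shape == (p, 3)
        assert model.y_loadings_.shape == (m, 3)
        assert model.x_scores_.shape == (n, 3)
        assert model.coef_.shape == (p, m)
        assert np.allclose(np.linalg.norm(model.x_weights_, axis=0), 1.0, atol=1e-12)

    def test_sign_convention(self, fitted):
        model, _, _ = fitted
        for a in range(model.n_components_):
            w = model.x_weights_[:, a]
            assert w[np.argmax(np.abs(w))] > 0

    def test_scores_orthogonal(self, fitted):
        model, _, _ = fitted
        T = model.x_scores_
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))

    def test_deflation_reconstructs_scaled_matrices(self, fitted):
        model, X, Y = fitted
        Xs = model.preprocess_.transform_x(X)
        Ys = model.preprocess_.transform_y(Y)
        assert np.allclose(
            Xs, model.x_scores_ @ model.x_loadings_.T + model.x_residuals_, atol=1e-10
        )
        assert np.allclose(
            Ys, model.x_scores_ @ model.y_loadings_.T + model.y_residuals_, atol=1e-10
        )

    def test_residuals_orthogonal_to_scores(self, fitted):
        model, _, _ = fitted
        assert np.max(np.abs(model.x_scores_.T @ model.x_residuals_)) < 1e-8
        assert np.max(np.abs(model.x_scores_.T @ model.y_residuals_)) < 1e-8

    def test_variance_accounting(self, fitted):
        model, _, _ = fitted
        for arr in (model.r2x_, model.r2y_):
            assert np.all(arr >= -1e-12)
        for cum in (model.r2x_cum_, model.r2y_cum_):
            assert np.all(np.diff(cum) >= -1e-12)
            assert cum[-1] <= 1.0 + 1e-12
        assert model.explained_y_ss_.sum() / model.total_y_ss_ == pytest.approx(
            model.r2y_cum_[-1], rel=1e-12
        )

    def test_predict_matches_fitted_values_on_training_rows(self, fitted):
        model, X, Y = fitted
        assert np.allclose(model.predict(X), model.fitted_values(), atol=1e-10)
        one = model.predict(X, n_components=1)
        assert not np.allclose(one, model.predict(X), atol=1e-6)

    def test_r2y_wrapper(self, fitted):
        model, _, _ = fitted
        per, overall = r2y(model)
        assert len(per) == 3
        assert overall == pytest.approx(model.r2y_cum_[-1])


def test_first_weight_is_dominant_singular_vector(rng):
    X, Y = _random_problem(rng, n=30, p=6, m=4)
    model = PLSRegressionNIPALS(n_components=1).fit(X, Y)
    Xs, Ys, _ = center_scale(X, Y)
    U, _, _ = np.linalg.svd(Xs.T @ Ys, full_matrices=False)
    w_svd = U[:, 0]
    if w_svd[np.argmax(np.abs(w_svd))] < 0:
        w_svd = -w_svd
    assert np.allclose(model.x_weights_[:, 0], w_svd, atol=1e-8)


def test_single_response_path(rng):
    X = rng.normal(size=(25, 6))
    y = X[:, 0] - 2 * X[:, 3] + 0.1 * rng.normal(size=25)
    model = PLSRegressionNIPALS(n_components=2).fit(X, y)
    assert model.y_loadings_.shape == (1, 2)
    assert model.r2y_cum_[-1] > 0.9
    assert model.predict(X).shape == (25, 1)


def test_full_rank_model_matches_ols(rng):
    X, Y = _random_problem(rng, n=40, p=5, m=2)
    model = PLSRegressionNIPALS(n_components=5).fit(X, Y)
    Xc = np.column_stack([np.ones(40), X])
    coef, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
    yhat_ols = Xc @ coef
    assert np.allclose(model.fitted_values(), yhat_ols, atol=1e-8)


def test_prediction_invariant_to_column_affine_transforms(rng):
    X, Y = _random_problem(rng)
    scalepos = rng.uniform(0.5, 4.0, size=X.shape[1])
    shift = rng.normal(size=X.shape[1])
    Xt = X * scalepos + shift
    a = PLSRegressionNIPALS(n_components=2).fit(X, Y)
    b = PLSRegressionNIPALS(n_components=2).fit(Xt, Y)
    assert np.allclose(a.predict(X), b.predict(Xt), atol=1e-8)


def test_noiseless_latent_data_reconstructed_exactly(linear_noiseless_dataset, linear_schema):
    records, responses, truth, cfg = linear_noiseless_dataset
    X = ag.build_design_matrix(records, linear_schema).values
    model = PLSRegressionNIPALS(n_components=2).fit(X, responses.values)
    resid = model.fitted_values() - responses.values.to_numpy()
    denom = np.abs(responses.values.to_numpy()).max()
    assert np.max(np.abs(resid)) / denom < 1e-10
    assert model.r2y_cum_[-1] > 1 - 1e-12


class TestValidation:
    def test_too_many_components(self, rng):
        X, Y = _random_problem(rng, n=6, p=4)
        with pytest.raises(ValueError, match="n_components"):
            PLSRegressionNIPALS(n_components=6).fit(X, Y)

    def test_predict_before_fit(self, rng):
        with pytest.raises(RuntimeError, match="not fitted"):
            PLSRegressionNIPALS().predict(rng.normal(size=(3, 4)))

    def test_column_mismatch_on_predict(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 3)), columns=["a", "b", "c"])
        Y = rng.normal(size=(12, 2))
        model = PLSRegressionNIPALS(n_components=2).fit(X, Y)
        with pytest.raises(ValueError, match="column"):
            model.predict(X.rename(columns={"c": "z"}))

    def test_bad_truncation_argument(self, rng):
        X, Y = _random_problem(rng)
        model = PLSRegressionNIPALS(n_components=2).fit(X, Y)
        with pytest.raises(ValueError):
            model.predict(X, n_components=3)

    def test_sklearn_param_protocol(self):
        model = PLSRegressionNIPALS(n_components=3, scale_y=False)
        params = model.get_params()
        assert params["n_components"] == 3 and params["scale_y"] is False
        cloned = clone(model)
        assert cloned.get_params() == params
        model.set_params(n_components=1)
        assert model.n_components == 1


class TestHotelling:
    def test_limit_matches_f_quantile(self, rng):
        X, Y = _random_problem(rng, n=24)
        model = PLSRegressionNIPALS(n_components=2).fit(X, Y)
        ls = hotelling_ellipse(model, alpha=0.05)
        n, k = 24, 2
        expected = k * (n**2 - 1) / (n * (n - k)) * stats.f.ppf(0.95, k, n - k)
        assert ls.t2_limit == pytest.approx(expected, rel=1e-12)
        assert ls.semi_axes == pytest.approx(ls.score_std * np.sqrt(expected), rel=1e-12)
        assert np.array_equal(ls.outside, ls.t2 > ls.t2_limit)

    def test_flagged_fraction_approaches_alpha(self):
        rng = np.random.default_rng(7)
        n = 2000
        X = rng.normal(size=(n, 10))
        B = rng.normal(size=(10, 3))
        Y = X @ B + rng.normal(size=(n, 3))
        model = PLSRegressionNIPALS(n_components=2).fit(X, Y)
        frac = hotelling_ellipse(model, alpha=0.05).outside.mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_requires_two_components(self, rng):
        X, Y = _random_problem(rng)
        model = PLSRegressionNIPALS(n_components=1).fit(X, Y)
        with pytest.raises(ValueError, match="2 components"):
            hotelling_ellipse(model)

    def test_bad_alpha(self, rng):
        X, Y = _random_problem(rng)
        model = PLSRegressionNIPALS(n_components=2).fit(X, Y)
        with pytest.raises(ValueError, match="alpha"):
            hotelling_ellipse(model, alpha=0.0)


def test_nipals_pls_wrapper_equivalent(rng):
    X, Y = _random_problem(rng)
    Xs, Ys, _ = center_scale(X, Y)
    a = nipals_pls(Xs, Ys, n_components=2)
    b = PLSRegressionNIPALS(n_components=2).fit(Xs, Ys)
    assert np.allclose(a.coef_, b.coef_, atol=1e-12)
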