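"""Cross-validated Q2, component selection, VIP filtering and RMSRE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import agropls as ag
from agropls.model_selection import (
    CVResult,
    VIPFilterPLS,
    VIPResult,
    _make_folds,
    crossval_q2,
    q2_simple,
    rmsre,
    select_components,
    vip,
    vip_filter_refit,
)
from agropls.pls_core import PLSRegressionNIPALS
from agropls.suite import _usable_columns


class TestRMSRE:
    def test_worked_example_ten_percent(self):
        assert rmsre([100, 100, 100, 100], [90, 110, 90, 110]) == pytest.approx(10.0)

    def test_worked_example_mixed_magnitudes(self):
        # relative errors 0.5, 0.25, 0.25, 0.5 -> 100*sqrt(0.15625)
        assert rmsre([2, 4, 8, 10], [3, 5, 10, 15]) == pytest.approx(
            39.528470752104741, rel=1e-12
        )

    def test_perfect_prediction_is_zero(self):
        assert rmsre([1.5, 2.5], [1.5, 2.5]) == 0.0

    def test_zero_observed_raises(self):
        with pytest.raises(ValueError, match="zero"):
            rmsre([1.0, 0.0], [1.0, 1.0])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            rmsre([1.0, 2.0], [1.0])

    @given(
        st.lists(st.floats(0.5, 100), min_size=2, max_size=10),
        st.floats(0.1, 50),
    )
    @settings(deadline=None, max_examples=50)
    def test_scale_invariance(self, y, c):
        y = np.asarray(y)
        yhat = y * 1.1
        assert rmsre(c * y, c * yhat) == pytest.approx(rmsre(y, yhat), rel=1e-9)


class TestFolds:
    def test_every_row_held_out_once_and_sizes_balanced(self):
        labels = _make_folds(34, 7, seed=3)
        assert labels.shape == (34,)
        counts = np.bincount(labels, minlength=7)
        assert counts.sum() == 34
        assert counts.max() - counts.min() <= 1

    def test_seed_determinism(self):
        assert np.array_equal(_make_folds(20, 5, seed=9), _make_folds(20, 5, seed=9))
        assert not np.array_equal(_make_folds(20, 5, seed=9), _make_folds(20, 5, seed=10))


def _problem(rng, n=12, p=4, m=1, noise=0.3):
    X = rng.normal(size=(n, p))
    B = rng.normal(size=(p, m))
    Y = X @ B + noise * rng.normal(size=(n, m))
    return X, Y


class TestCrossvalQ2:
    def test_loo_press_equals_brute_force_refit(self, rng):
        X, Y = _problem(rng)
        n = X.shape[0]
        cv = crossval_q2(X, Y, a_max=2, k=n, seed=0)
        full = PLSRegressionNIPALS(n_components=2).fit(X, Y)
        for a in (1, 2):
            press = np.zeros(Y.shape[1])
            for i in range(n):
                train = np.arange(n) != i
                sub = PLSRegressionNIPALS(n_components=2).fit(X[train], Y[train])
                err = (Y[~train] - sub.predict(X[~train], n_components=a))
                press += ((err / full.preprocess_.y_std) ** 2).sum(axis=0)
            assert np.allclose(cv.press[a - 1], press, rtol=1e-10)

    def test_deterministic_for_fixed_seed(self, rng):
        X, Y = _problem(rng, n=20, p=5, m=2)
        a = crossval_q2(X, Y, a_max=2, k=7, seed=4)
        b = crossval_q2(X, Y, a_max=2, k=7, seed=4)
        assert np.array_equal(a.folds, b.folds)
        assert np.allclose(a.press, b.press)

    def test_strong_signal_gives_high_q2(self, rng):
        X, Y = _problem(rng, n=30, p=5, m=2, noise=0.1)
        cv = crossval_q2(X, Y, a_max=3, k=7, seed=0)
        assert cv.q2_overall_cum[-1] > 0.9
        # cumulative per-response series aligns with the matrix
        s = cv.q2_cum_series(3)
        assert np.allclose(s.to_numpy(), cv.q2_cum[2])

    def test_pure_noise_q2_not_positive_on_average(self):
        vals = []
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(20, 6))
            Y = rng.normal(size=(20, 2))
            cv = crossval_q2(X, Y, a_max=1, k=7, seed=seed)
            vals.append(cv.q2_overall_per_component[0])
        assert np.mean(vals) < 0

    def test_noiseless_data_q2_near_one_and_finite(
        self, linear_noiseless_dataset, linear_schema
    ):
        records, responses, _, _ = linear_noiseless_dataset
        X = ag.build_design_matrix(records, linear_schema).values
        cv = crossval_q2(X, responses.values, a_max=3, k=7, seed=0)
        assert np.all(np.isfinite(cv.q2_cum))
        assert cv.q2_overall_cum[1] > 1 - 1e-8

    def test_a_max_bound_enforced(self, rng):
        X, Y = _problem(rng, n=10, p=9)
        # k=2 -> fold-size bound n - ceil(n/k) - 1 = 4
        with pytest.raises(ValueError, match="a_max"):
            crossval_q2(X, Y, a_max=5, k=2, seed=0)
        with pytest.raises(ValueError, match="folds"):
            crossval_q2(X, Y, a_max=1, k=11, seed=0)

    def test_degenerate_fold_is_an_error(self, rng):
        n = 8
        X = rng.normal(size=(n, 3))
        X[:, 2] = 0.0
        X[5, 2] = 1.0  # dummy with a single positive row
        Y = rng.normal(size=(n, 1))
        with pytest.raises(ValueError, match="degenerate fold"):
            crossval_q2(X, Y, a_max=1, k=n, seed=0)

    def test_q2_simple_convention(self, rng):
        X, Y = _problem(rng, n=25, p=5, m=2)
        cv = crossval_q2(X, Y, a_max=2, k=5, seed=1)
        expected = 1.0 - cv.press[1].sum() / cv.ss_prev[0].sum()
        assert q2_simple(cv, 2) == pytest.approx(expected, rel=1e-12)


def _cv_stub(q2_overall):
    q2_overall = np.asarray(q2_overall, dtype=float)
    a = len(q2_overall)
    z = np.zeros((a, 1))
    return CVResult(
        folds=np.zeros(5, int), press=z, ss_prev=z, q2_per_component=z,
        q2_overall_per_component=q2_overall, q2_cum=z,
        q2_overall_cum=np.zeros(a), response_names=["y"], seed=0, n_folds=5,
    )


class TestSelectComponents:
    def test_stops_at_first_failure(self):
        assert select_components(_cv_stub([0.3, 0.2, 0.01, 0.4])) == (2, False)

    def test_floor_at_one_with_flag(self):
        assert select_components(_cv_stub([0.01, 0.5])) == (1, True)

    def test_limit_is_strict(self):
        assert select_components(_cv_stub([0.05])) == (1, True)
        assert select_components(_cv_stub([0.050001])) == (1, False)

    def test_all_pass(self):
        assert select_components(_cv_stub([0.5, 0.4, 0.1])) == (3, False)


class TestVIP:
    def test_normalization_identity(self, rng):
        X, Y = _problem(rng, n=25, p=7, m=3, noise=0.5)
        model = PLSRegressionNIPALS(n_components=2).fit(X, Y)
        scores = vip(model).scores
        assert (scores**2).mean() == pytest.approx(1.0, abs=1e-10)
        assert scores.max() >= 1.0

    def test_informative_variable_outranks_noise(self, rng):
        n = 60
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=["sig", "n1", "n2", "n3"])
        Y = 3 * X["sig"].to_numpy()[:, None] + 0.2 * rng.normal(size=(n, 1))
        model = PLSRegressionNIPALS(n_components=1).fit(X, Y)
        scores = vip(model).scores
        assert scores["sig"] > 1.0
        assert scores["sig"] > scores[["n1", "n2", "n3"]].max()

    def test_threshold_boundary_retained(self):
        res = VIPResult(pd.Series({"a": 1.0, "b": 0.999999, "c": 1.2}))
        assert res.retained(1.0) == ["a", "c"]


@pytest.fixture(scope="module")
def recovery_fit():
    cfg = ag.SyntheticConfig.recovery()
    records, responses, truth = ag.generate_synthetic_farms(cfg, seed=2024)
    schema = ag.default_schema()
    X = ag.build_design_matrix(records, schema).values
    X, _ = _usable_columns(X, k=7)
    est = VIPFilterPLS(random_state=0, label="recovery").fit(X, responses.values)
    return est, X, responses, truth


class TestVIPFilterPLS:
    def test_fitted_attributes_consistent(self, recovery_fit):
        est, X, responses, truth = recovery_fit
        assert set(est.retained_) <= set(X.columns)
        assert est.support_.sum() == len(est.retained_)
        assert list(est.vip_.index) == list(X.columns)
        assert est.n_components_ == est.estimator_.n_components_
        assert list(est.estimator_.feature_names_in_) == est.retained_

    def test_report_contents(self, recovery_fit):
        est, X, responses, _ = recovery_fit
        rep = est.report_
        assert rep.label == "recovery"
        assert len(rep.farm_ids) == X.shape[0]
        assert len(rep.r2y) == len(rep.q2y) == len(rep.rmsre) == 7
        assert 0 < rep.r2y_overall <= 1
        assert rep.q2y_overall <= rep.r2y_overall + 1e-12
        assert (rep.rmsre > 0).all()
        assert len(rep.predictions) == X.shape[0] * 7

    def test_recovers_active_variables(self, recovery_fit):
        est, _, _, truth = recovery_fit
        active = set(truth.config.active_of)
        found = active & set(est.retained_)
        assert len(found) >= 4

    def test_predict_shape(self, recovery_fit):
        est, X, responses, _ = recovery_fit
        yhat = est.predict(X)
        assert yhat.shape == responses.values.shape

    def test_functional_wrapper_matches_estimator(self, recovery_fit):
        est, X, responses, _ = recovery_fit
        rep, retained = vip_filter_refit(X, responses.values, seed=0, label="recovery")
        assert retained == est.retained_
        pd.testing.assert_series_equal(rep.r2y, est.report_.r2y)

    def test_explicit_a_max_over_bound_rejected(self, rng):
        X, Y = _problem(rng, n=10, p=6, m=2)
        with pytest.raises(ValueError, match="a_max"):
            VIPFilterPLS(a_max=8, k=5).fit(X, Y)
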