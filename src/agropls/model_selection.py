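"""Cross-validated predictive ability (Q2Y), component selection, VIP-based
variable selection and the relative prediction error metric.

Cross-validation follows the chemometric convention: for each candidate
component count *a*, every fold's model is refitted from scratch (including the
centring/scaling statistics, so no information leaks from held-out rows) and
the held-out rows are predicted. The predictive residual sum of squares
PRESS_a is compared against the residual sum of squares of the full fit after
a-1 components, giving a per-component Q2; the cumulative Q2 is the
multiplicative combination ``1 - prod_a PRESS_a / SS_{a-1}`` (a simple
``1 - PRESS_A / SS_0`` variant is available). Q2 is never floored at zero:
negative values mean the component predicts worse than the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .pls_core import PLSRegressionNIPALS, center_scale, _as_2d, _column_names

__all__ = [
    "CVResult",
    "VIPResult",
    "FitReport",
    "VIPFilterPLS",
    "crossval_q2",
    "select_components",
    "vip",
    "vip_filter_refit",
    "rmsre",
]


@dataclass
class CVResult:
    """Cross-validation output up to A_max components."""

    folds: np.ndarray  # fold label per row
    press: np.ndarray  # (A, m) PRESS per component and response
    ss_prev: np.ndarray  # (A, m) full-fit residual SS after a-1 components
    q2_per_component: np.ndarray  # (A, m)
    q2_overall_per_component: np.ndarray  # (A,)
    q2_cum: np.ndarray  # (A, m) cumulative per response
    q2_overall_cum: np.ndarray  # (A,)
    response_names: list[str]
    seed: int
    n_folds: int

    def q2_cum_series(self, a: int) -> pd.Series:
        """Cumulative Q2 per response at a components (1-based)."""
        return pd.Series(self.q2_cum[a - 1], index=self.response_names)


@dataclass
class VIPResult:
    """Variable importance in the projection, one score per X-variable.

    Satisfies the normalization identity mean(VIP^2) = 1, hence at least one
    variable always scores >= 1.
    """

    scores: pd.Series

    def retained(self, threshold: float = 1.0) -> list[str]:
        """Variables with VIP >= threshold (scores equal to the threshold are
        kept; only strictly smaller ones are eliminated)."""
        return [str(n) for n, v in self.scores.items() if v >= threshold]


@dataclass
class FitReport:
    """Metrics for one fitted model: fit (R2Y), prediction (Q2Y) and relative
    error (RMSRE, %) per response plus overall."""

    label: str
    farm_ids: list[str]
    retained: list[str]
    n_components: int
    r2y: pd.Series
    r2y_overall: float
    q2y: pd.Series
    q2y_overall: float
    rmsre: pd.Series
    vip: pd.Series  # first-round VIP scores (all variables)
    dropped_constant: list[str] = field(default_factory=list)
    component_floor_flag: bool = False
    predictions: pd.DataFrame | None = None  # tidy farm x response obs/pred


def rmsre(y, yhat) -> float:
    """Root mean square relative error, in percent.

    ``100 * sqrt(mean(((y - yhat) / y)^2))`` over the observations. Undefined
    (raises) when any observed value is zero.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted vectors differ in length")
    if np.any(y == 0):
        raise ValueError("RMSRE undefined: observed value equal to zero")
    return 100.0 * math.sqrt(float(np.mean(((y - yhat) / y) ** 2)))


def _make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded shuffle followed by contiguous-block assignment; fold sizes
    differ by at most one and every row is held out exactly once."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    for f, block in enumerate(np.array_split(perm, k)):
        labels[block] = f
    return labels


def crossval_q2(
    X,
    Y,
    a_max: int,
    k: int = 7,
    seed: int = 0,
    scale_y: bool = True,
) -> CVResult:
    """K-fold cross-validated PRESS and Q2 for 1..a_max components.

    Per-component Q2_a = 1 - PRESS_a / SS_{a-1}, with SS_{a-1} the residual
    sum of squares of the full fit after a-1 components (SS_0 = total SS of
    the scaled responses). Held-out errors are expressed on the full-fit
    response scale so PRESS and SS are commensurate. Deterministic for a
    fixed seed.
    """
    ynames = _column_names(Y, "y")
    Xa, Ya = _as_2d(X), _as_2d(Y)
    n, p = Xa.shape
    m = Ya.shape[1]
    if k > n:
        raise ValueError(f"k={k} folds exceed n={n} rows")
    if k < 2:
        raise ValueError("need at least 2 folds")
    max_allowed = min(n - math.ceil(n / k) - 1, p)
    if a_max > max_allowed:
        raise ValueError(f"a_max={a_max} exceeds the fold-size bound {max_allowed}")
    if a_max < 1:
        raise ValueError("a_max must be >= 1")

    folds = _make_folds(n, k, seed)

    # full fit: residual SS per response after each component count
    full = PLSRegressionNIPALS(n_components=a_max, scale_y=scale_y).fit(Xa, Ya)
    Ys_full = full.preprocess_.transform_y(Ya)
    ss0 = (Ys_full**2).sum(axis=0)
    # SS after a components = SS0 - cumulative explained SS per column
    expl_col = np.array(
        [full.x_scores_[:, a] @ full.x_scores_[:, a] * full.y_loadings_[:, a] ** 2
         for a in range(a_max)]
    )
    ss_after = ss0 - np.cumsum(expl_col, axis=0)  # (A, m)
    ss_prev = np.vstack([ss0, ss_after[:-1]]) if a_max > 1 else ss0[None, :]

    press = np.zeros((a_max, m))
    for f in range(k):
        test = folds == f
        train = ~test
        Xtr, Ytr = Xa[train], Ya[train]
        # degenerate-fold guard: scaling is recomputed inside the fold
        if np.any(Xtr.std(axis=0, ddof=1) == 0) or np.any(Ytr.std(axis=0, ddof=1) == 0):
            raise ValueError(f"degenerate fold {f}: constant column within training rows")
        sub = PLSRegressionNIPALS(n_components=a_max, scale_y=scale_y).fit(Xtr, Ytr)
        for a in range(1, a_max + 1):
            yhat = sub.predict(Xa[test], n_components=a)
            err = (Ya[test] - yhat) / full.preprocess_.y_std
            press[a - 1] += (err**2).sum(axis=0)

    # a vanished residual (perfect fit at a-1 components) means the extra
    # component cannot improve anything: ratio 1, Q2 contribution 0
    ratio = np.divide(press, ss_prev, out=np.ones_like(press), where=ss_prev > 0)
    press_tot, ss_tot = press.sum(axis=1), ss_prev.sum(axis=1)
    ratio_tot = np.divide(press_tot, ss_tot, out=np.ones_like(press_tot), where=ss_tot > 0)
    q2_comp = 1.0 - ratio
    q2_comp_overall = 1.0 - ratio_tot
    q2_cum = 1.0 - np.cumprod(ratio, axis=0)
    q2_cum_overall = 1.0 - np.cumprod(ratio_tot)
    return CVResult(
        folds=folds,
        press=press,
        ss_prev=ss_prev,
        q2_per_component=q2_comp,
        q2_overall_per_component=q2_comp_overall,
        q2_cum=q2_cum,
        q2_overall_cum=q2_cum_overall,
        response_names=ynames,
        seed=seed,
        n_folds=k,
    )


def q2_simple(cv: CVResult, a: int) -> float:
    """Alternative cumulative Q2 convention: 1 - PRESS_a / SS_0 (overall)."""
    return 1.0 - float(cv.press[a - 1].sum() / cv.ss_prev[0].sum())


def select_components(cv: CVResult, limit: float = 0.05) -> tuple[int, bool]:
    """Largest a such that every component 1..a clears the per-component Q2
    limit; at least one component is always retained, with a flag when even
    the first fails."""
    a_star = 0
    for a, q2 in enumerate(cv.q2_overall_per_component, start=1):
        if q2 > limit:
            a_star = a
        else:
            break
    if a_star == 0:
        return 1, True
    return a_star, False


def vip(model: PLSRegressionNIPALS) -> VIPResult:
    """Variable importance in the projection over the model's components.

    VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ) with unit-norm
    weights w_a and SSY_a the Y sum of squares explained by component a.
    """
    model._check_fitted()
    W = model.x_weights_
    ssy = model.explained_y_ss_
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model explains no Y variance; VIP undefined")
    p = W.shape[0]
    scores = np.sqrt(p * (W**2 @ ssy) / total)
    return VIPResult(pd.Series(scores, index=list(model.feature_names_in_)))


class VIPFilterPLS(BaseEstimator, RegressorMixin):
    """The two-round filter-and-refit workflow as a single estimator.

    Round one fits a PLS model on all variables with the component count
    chosen by cross-validation, then eliminates every variable with VIP
    strictly below ``vip_threshold``. Round two re-selects the component count
    and refits on the surviving variables; metrics (R2Y, Q2Y, RMSRE) are
    reported for the final model. Exactly two rounds, no iteration.

    Parameters
    ----------
    vip_threshold : float
        Variables with VIP < threshold are eliminated (== is retained).
    k : int
        Cross-validation folds.
    q2_limit : float
        Per-component Q2 limit for component selection.
    a_max : int or None
        Candidate component cap; ``None`` uses ``min(4, fold-size bound, p)``.
    scale_y : bool
        Unit-variance scale responses.
    random_state : int
        Seed for the CV fold shuffles.

    Attributes
    ----------
    support_ : boolean ndarray over input variables (retained mask)
    retained_ : list of retained variable names
    vip_ : pandas.Series of first-round VIP scores
    n_components_ : final component count
    estimator_ : the final fitted :class:`PLSRegressionNIPALS`
    report_ : :class:`FitReport`
    """

    def __init__(self, vip_threshold: float = 1.0, k: int = 7, q2_limit: float = 0.05,
                 a_max: int | None = None, scale_y: bool = True, random_state: int = 0,
                 label: str = "model"):
        self.vip_threshold = vip_threshold
        self.k = k
        self.q2_limit = q2_limit
        self.a_max = a_max
        self.scale_y = scale_y
        self.random_state = random_state
        self.label = label

    def _a_max(self, n: int, p: int) -> int:
        bound = min(n - math.ceil(n / self.k) - 1, p)
        if self.a_max is not None:
            if self.a_max > bound:
                raise ValueError(f"a_max={self.a_max} exceeds the CV bound {bound}")
            return self.a_max
        return max(1, min(4, bound))

    def fit(self, X, Y):
        xnames = _column_names(X, "x")
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(_as_2d(X), columns=xnames)
        ynames = _column_names(Y, "y")
        Ya = pd.DataFrame(_as_2d(Y), columns=ynames, index=Xdf.index)
        n, p = Xdf.shape
        if p < 2:
            raise ValueError("need at least 2 variables to filter")
        a_max = self._a_max(n, p)

        cv1 = crossval_q2(Xdf, Ya, a_max, k=self.k, seed=self.random_state,
                          scale_y=self.scale_y)
        a1, flag1 = select_components(cv1, self.q2_limit)
        full = PLSRegressionNIPALS(n_components=a1, scale_y=self.scale_y).fit(Xdf, Ya)
        vip_res = vip(full)
        retained = vip_res.retained(self.vip_threshold)
        # normalization identity guarantees max VIP >= 1, so the filter can
        # never empty the variable set at the default threshold
        assert retained, "VIP filter emptied the variable set (identity violated)"

        Xr = Xdf.loc[:, retained]
        a_max2 = min(a_max, len(retained))
        self.cv_full_ = cv1
        if len(retained) >= 2:
            cv2 = crossval_q2(Xr, Ya, a_max2, k=self.k, seed=self.random_state,
                              scale_y=self.scale_y)
            a2, flag2 = select_components(cv2, self.q2_limit)
        else:
            cv2 = crossval_q2(Xr, Ya, 1, k=self.k, seed=self.random_state,
                              scale_y=self.scale_y)
            a2, flag2 = 1, False
        final = PLSRegressionNIPALS(n_components=a2, scale_y=self.scale_y).fit(Xr, Ya)

        Yarr = Ya.to_numpy()
        fitted = final.fitted_values()
        rmsre_per = pd.Series(
            {ynames[j]: rmsre(Yarr[:, j], fitted[:, j]) for j in range(Yarr.shape[1])}
        )
        rows = list(Xdf.index.astype(str))
        pred_rows = []
        for i, farm in enumerate(rows):
            for j, resp in enumerate(ynames):
                pred_rows.append(
                    {"farm_id": farm, "response": resp,
                     "observed": Yarr[i, j], "predicted": fitted[i, j]}
                )
        self.support_ = np.array([name in set(retained) for name in xnames])
        self.retained_ = retained
        self.vip_ = vip_res.scores
        self.n_components_ = a2
        self.estimator_ = final
        self.cv_final_ = cv2
        self.report_ = FitReport(
            label=self.label,
            farm_ids=rows,
            retained=retained,
            n_components=a2,
            r2y=final.r2y_per_response_.copy(),
            r2y_overall=float(final.r2y_cum_[-1]),
            q2y=cv2.q2_cum_series(a2),
            q2y_overall=float(cv2.q2_overall_cum[a2 - 1]),
            rmsre=rmsre_per,
            vip=vip_res.scores.copy(),
            component_floor_flag=flag1 or flag2,
            predictions=pd.DataFrame(pred_rows),
        )
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "estimator_"):
            raise RuntimeError("estimator is not fitted")
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
            _as_2d(X), columns=list(self.vip_.index)
        )
        return self.estimator_.predict(Xdf.loc[:, self.retained_])


def vip_filter_refit(
    X,
    Y,
    threshold: float = 1.0,
    k: int = 7,
    seed: int = 0,
    q2_limit: float = 0.05,
    a_max: int | None = None,
    label: str = "model",
) -> tuple[FitReport, list[str]]:
    """Functional wrapper over :class:`VIPFilterPLS`; returns the report and
    the retained variable names."""
    est = VIPFilterPLS(
        vip_threshold=threshold, k=k, q2_limit=q2_limit, a_max=a_max,
        random_state=seed, label=label,
    ).fit(X, Y)
    return est.report_, est.retained_
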