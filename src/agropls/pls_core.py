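"""Multi-response PLS regression (NIPALS) with scaling, prediction and
variance accounting.

The model relates an n x p explanatory matrix X to an n x m response matrix Y
through shared latent score vectors:

    X_s = T P' + E        Y_s = T Q' + F

where X_s, Y_s are the column-centred, unit-variance-scaled matrices, T holds
the X-scores, P and Q the X- and Y-loadings, and E, F the residuals.
Components are extracted one at a time by the NIPALS power iteration on the
cross-covariance, deflating both X and Y (classical PLS2); a single response
column reduces to PLS1 through the same code path.

Scaling follows the chemometric convention of unit-variance scaling for every
column, dummies included; this inflates the influence of rare categories and is
kept deliberately (configurable via ``scale_y`` for the responses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "PreprocessModel",
    "PLSRegressionNIPALS",
    "LatentSpace",
    "ConvergenceError",
    "center_scale",
    "nipals_pls",
    "predict",
    "r2y",
    "hotelling_ellipse",
]


class ConvergenceError(RuntimeError):
    """The NIPALS inner iteration failed to converge."""


@dataclass
class PreprocessModel:
    """Training-set column means and standard deviations for X and Y.

    Standard deviations use the n-1 (sample) convention. Applying
    :meth:`transform_x` / :meth:`transform_y` to the training data yields
    columns with mean 0 and SD 1.
    """

    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray

    def transform_x(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) / self.x_std

    def transform_y(self, Y: np.ndarray) -> np.ndarray:
        return (np.asarray(Y, dtype=float) - self.y_mean) / self.y_std

    def inverse_y(self, Ys: np.ndarray) -> np.ndarray:
        return np.asarray(Ys, dtype=float) * self.y_std + self.y_mean


def _column_names(X, fallback: str) -> list[str]:
    if isinstance(X, pd.DataFrame):
        return [str(c) for c in X.columns]
    if isinstance(X, pd.Series):
        return [str(X.name) if X.name is not None else f"{fallback}0"]
    arr = np.asarray(X)
    ncol = 1 if arr.ndim == 1 else arr.shape[1]
    return [f"{fallback}{j}" for j in range(ncol)]


def _as_2d(M) -> np.ndarray:
    arr = np.asarray(M, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def center_scale(X, Y, scale_y: bool = True):
    """Centre and unit-variance scale X and Y on their own statistics.

    Returns ``(Xs, Ys, PreprocessModel)``. Raises ``ValueError`` naming the
    first constant column found (a constant column cannot be scaled).
    """
    xnames = _column_names(X, "x")
    ynames = _column_names(Y, "y")
    Xa, Ya = _as_2d(X), _as_2d(Y)
    if Xa.shape[0] < 2:
        raise ValueError("need at least 2 rows to centre and scale")
    if Xa.shape[0] != Ya.shape[0]:
        raise ValueError("X and Y row counts differ")

    def _stats(M, names, scale):
        mean = M.mean(axis=0)
        std = M.std(axis=0, ddof=1)
        bad = np.flatnonzero(std == 0)
        if bad.size:
            raise ValueError(f"constant column {names[bad[0]]!r} cannot be scaled")
        if not scale:
            std = np.ones_like(std)
        return mean, std

    x_mean, x_std = _stats(Xa, xnames, True)
    y_mean, y_std = _stats(Ya, ynames, scale_y)
    pp = PreprocessModel(x_mean, x_std, y_mean, y_std)
    return pp.transform_x(Xa), pp.transform_y(Ya), pp


def _nipals_component(Xa, Ya, max_iter, tol, comp_index):
    """Extract one NIPALS component from the (deflated) Xa, Ya.

    Returns unit-norm weight w, scores t, X-loading p, Y-loading q.
    """
    m = Ya.shape[1]
    if m == 1:
        u = Ya[:, 0].copy()
    else:
        # warm start at the fixed point: the NIPALS iteration converges to the
        # dominant singular pair of X'Y, so seed u with the corresponding
        # Y-side direction (robust when the top singular values nearly tie,
        # where a cold power iteration stalls)
        _, sv, Vt = np.linalg.svd(Xa.T @ Ya, full_matrices=False)
        u = Ya @ Vt[0] if sv[0] > 0 else Ya[:, int(np.argmax((Ya**2).sum(axis=0)))].copy()
        if not np.any(u):
            u = Ya[:, int(np.argmax((Ya**2).sum(axis=0)))].copy()
    if m == 1:
        w = Xa.T @ u
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ConvergenceError(f"component {comp_index}: X carries no remaining variance")
        w /= nw
        t = Xa @ w
    else:
        for _ in range(max_iter):
            w = Xa.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ConvergenceError(f"component {comp_index}: X carries no remaining variance")
            w /= nw
            t = Xa @ w
            c = Ya.T @ t
            c /= np.linalg.norm(c)
            u_new = Ya @ c
            if np.linalg.norm(u_new - u) <= tol * max(np.linalg.norm(u_new), 1e-300):
                u = u_new
                break
            u = u_new
        else:
            raise ConvergenceError(
                f"NIPALS did not converge for component {comp_index} after {max_iter} iterations"
            )
    # deterministic sign: largest-magnitude weight element is positive
    j = int(np.argmax(np.abs(w)))
    if w[j] < 0:
        w = -w
        t = -t
    tt = float(t @ t)
    if tt == 0:
        raise ConvergenceError(f"component {comp_index}: zero score vector")
    p = Xa.T @ t / tt
    q = Ya.T @ t / tt
    return w, t, p, q


class PLSRegressionNIPALS(BaseEstimator, RegressorMixin):
    """Multi-response PLS regression fitted by NIPALS.

    Parameters
    ----------
    n_components : int
        Number of latent components A to extract (must satisfy
        ``A <= min(n - 1, p)``).
    scale_y : bool
        Unit-variance scale the response columns as well as X (the usual
        chemometric default).
    max_iter : int
        Cap on the inner power iteration per component.
    tol : float
        Relative convergence threshold on the change of the Y-score vector u.

    Attributes
    ----------
    x_weights_ : (p, A) ndarray
        Unit-norm X-weights W (sign-fixed: largest element positive).
    x_loadings_, y_loadings_ : ndarray
        P (p, A) and Q (m, A).
    x_scores_ : (n, A) ndarray
        Scores T; columns mutually orthogonal.
    x_residuals_, y_residuals_ : ndarray
        E and F after all A components (scaled space).
    coef_ : (p, m) ndarray
        Regression coefficients B mapping scaled X to scaled Y.
    r2x_, r2y_ : (A,) ndarray
        Per-component fractions of X / Y variance explained (scaled space).
    r2x_cum_, r2y_cum_ : (A,) ndarray
        Cumulative versions.
    r2y_per_response_ : pandas.Series
        Cumulative R2Y per response column.
    explained_y_ss_ : (A,) ndarray
        Absolute Y sum of squares explained per component (used by VIP).
    """

    def __init__(self, n_components: int = 2, scale_y: bool = True,
                 max_iter: int = 5000, tol: float = 1e-10):
        self.n_components = n_components
        self.scale_y = scale_y
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, Y):
        xnames = _column_names(X, "x")
        ynames = _column_names(Y, "y")
        rows = list(X.index) if isinstance(X, pd.DataFrame) else list(range(_as_2d(X).shape[0]))
        Xa, Ya = _as_2d(X), _as_2d(Y)
        n, p = Xa.shape
        m = Ya.shape[1]
        A = int(self.n_components)
        if A < 1:
            raise ValueError("n_components must be >= 1")
        if A > min(n - 1, p):
            raise ValueError(
                f"n_components={A} exceeds min(n-1, p) = {min(n - 1, p)} for n={n}, p={p}"
            )
        Xs, Ys, pp = center_scale(Xa, Ya, scale_y=self.scale_y)
        if not np.any(Xs):
            raise ValueError("scaled X is all zero")

        ssx_total = float((Xs**2).sum())
        ssy_total = float((Ys**2).sum())
        ssy_col_total = (Ys**2).sum(axis=0)

        W = np.zeros((p, A))
        P = np.zeros((p, A))
        Q = np.zeros((m, A))
        T = np.zeros((n, A))
        r2x = np.zeros(A)
        ssy_exp = np.zeros(A)
        ssy_exp_col = np.zeros((A, m))

        Xd, Yd = Xs.copy(), Ys.copy()
        for a in range(A):
            w, t, pvec, q = _nipals_component(Xd, Yd, self.max_iter, self.tol, a + 1)
            tt = float(t @ t)
            Xd -= np.outer(t, pvec)
            Yd -= np.outer(t, q)
            W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, pvec, q
            r2x[a] = tt * float(pvec @ pvec) / ssx_total
            ssy_exp_col[a] = tt * q**2
            ssy_exp[a] = ssy_exp_col[a].sum()

        self.preprocess_ = pp
        self.feature_names_in_ = np.asarray(xnames, dtype=object)
        self.response_names_in_ = np.asarray(ynames, dtype=object)
        self.row_index_ = rows
        self.n_components_ = A
        self.x_weights_, self.x_loadings_, self.y_loadings_, self.x_scores_ = W, P, Q, T
        self.x_residuals_, self.y_residuals_ = Xd, Yd
        # B = W (P'W)^{-1} Q'   (scaled space)
        self.x_rotations_ = W @ np.linalg.solve(P.T @ W, np.eye(A))
        self.coef_ = self.x_rotations_ @ Q.T
        self.r2x_ = r2x
        self.r2y_ = ssy_exp / ssy_total
        self.r2x_cum_ = np.cumsum(r2x)
        self.r2y_cum_ = np.cumsum(self.r2y_)
        self.explained_y_ss_ = ssy_exp
        self.total_y_ss_ = ssy_total
        with np.errstate(invalid="ignore"):
            percol = 1.0 - (Yd**2).sum(axis=0) / ssy_col_total
        self.r2y_per_response_ = pd.Series(percol, index=ynames)
        return self

    # -- prediction ---------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")

    def _check_columns(self, X):
        if isinstance(X, pd.DataFrame):
            got = [str(c) for c in X.columns]
            want = list(self.feature_names_in_)
            if got != want:
                raise ValueError(f"column mismatch: expected {want}, got {got}")

    def transform(self, X) -> np.ndarray:
        """Project new rows onto the latent space (scores)."""
        self._check_fitted()
        self._check_columns(X)
        Xs = self.preprocess_.transform_x(_as_2d(X))
        return Xs @ self.x_rotations_

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        """Predict responses in original units.

        ``n_components`` truncates the model to its first a components (useful
        for per-component cross-validation); default uses all of them.
        """
        self._check_fitted()
        self._check_columns(X)
        Xa = _as_2d(X)
        if Xa.shape[1] != self.coef_.shape[0]:
            raise ValueError(
                f"X has {Xa.shape[1]} columns, model expects {self.coef_.shape[0]}"
            )
        a = self.n_components_ if n_components is None else int(n_components)
        if not 1 <= a <= self.n_components_:
            raise ValueError(f"n_components must be in [1, {self.n_components_}]")
        scores = self.preprocess_.transform_x(Xa) @ self.x_rotations_
        Ys_hat = scores[:, :a] @ self.y_loadings_[:, :a].T
        return self.preprocess_.inverse_y(Ys_hat)

    def fitted_values(self) -> np.ndarray:
        """Fitted responses on the training rows, original units."""
        self._check_fitted()
        return self.preprocess_.inverse_y(self.x_scores_ @ self.y_loadings_.T)


@dataclass
class LatentSpace:
    """First two latent dimensions of a fitted model with the Hotelling T2
    confidence ellipse used to flag extreme farms in score plots."""

    scores: np.ndarray  # n x 2
    score_std: np.ndarray  # SDs of the two score columns
    semi_axes: np.ndarray  # ellipse semi-axes
    t2: np.ndarray  # per-row Hotelling statistic
    t2_limit: float
    outside: np.ndarray  # boolean mask: rows beyond the limit
    alpha: float


def hotelling_ellipse(model: PLSRegressionNIPALS, alpha: float = 0.05) -> LatentSpace:
    """Hotelling T2 confidence region on the first two score columns.

    The limit uses the standard small-sample form
    ``T2_lim = k(n^2-1) / (n(n-k)) * F(1-alpha; k, n-k)`` with k = 2 latent
    dimensions; rows with T2 strictly above the limit are flagged. For large n
    and standard-normal scores the flagged fraction approaches ``alpha``.
    """
    model._check_fitted()
    if model.n_components_ < 2:
        raise ValueError("Hotelling ellipse needs at least 2 components")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    T2dim = model.x_scores_[:, :2]
    n = T2dim.shape[0]
    k = 2
    s = T2dim.std(axis=0, ddof=1)
    if np.any(s == 0):
        # degenerate: no spread in a latent dimension; nothing can be outside
        t2 = np.zeros(n)
        return LatentSpace(T2dim, s, np.zeros(2), t2, 0.0, np.zeros(n, bool), alpha)
    t2 = ((T2dim / s) ** 2).sum(axis=1)
    fq = stats.f.ppf(1 - alpha, k, n - k)
    limit = k * (n**2 - 1) / (n * (n - k)) * fq
    return LatentSpace(
        scores=T2dim,
        score_std=s,
        semi_axes=s * np.sqrt(limit),
        t2=t2,
        t2_limit=float(limit),
        outside=t2 > limit,
        alpha=alpha,
    )


# -- thin functional wrappers -------------------------------------------------


def nipals_pls(Xs, Ys, n_components: int, max_iter: int = 5000, tol: float = 1e-10):
    """Fit PLS on already-scaled matrices and return the fitted estimator.

    Convenience wrapper: the estimator re-centres internally, which leaves
    already centred/scaled input unchanged up to the stored statistics.
    """
    return PLSRegressionNIPALS(
        n_components=n_components, max_iter=max_iter, tol=tol
    ).fit(Xs, Ys)


def predict(model: PLSRegressionNIPALS, Xnew) -> np.ndarray:
    return model.predict(Xnew)


def r2y(model: PLSRegressionNIPALS) -> tuple[pd.Series, float]:
    """Cumulative R2Y per response and overall for a fitted model."""
    model._check_fitted()
    return model.r2y_per_response_.copy(), float(model.r2y_cum_[-1])
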