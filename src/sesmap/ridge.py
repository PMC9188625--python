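"""Multi-output ridge regression: the core pattern-learning estimator.

The estimator minimizes, over W in R^{p x k},

    (1 / (2 n)) * ||Y - X W||_F^2  +  (alpha / 2) * ||W||_F^2

on standardized, intercept-free data.  The closed-form minimizer is
W = (X'X/n + alpha I)^{-1} X'Y/n; a deterministic cyclic coordinate-descent
solver is provided as an alternative route to the same optimum.  Because
the Frobenius penalty separates across outcome columns, column j of the
multi-output solution equals the single-output ridge fit of indicator j
alone — an exact algebraic identity this package's tests lean on.

Note on conventions: this objective normalizes the residual sum of squares
by n, so alpha = 0.01 here corresponds to alpha_unnormalized = n * 0.01 in
solvers that penalize the raw RSS (e.g. ``sklearn.linear_model.Ridge``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression
from sklearn.metrics import (
    explained_variance_score,
    mean_absolute_error,
    mean_squared_error,
    r2_score,
)
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor

from .preprocess import ColumnStandardizer, ConfoundResidualizer

__all__ = [
    "MultiTaskRidge",
    "metric_report",
    "crossval_benchmark",
    "MODEL_REGISTRY",
]

METRICS = (
    "pearson_r",
    "explained_variance_score",
    "mean_absolute_error",
    "coefficient_of_determination",
    "mean_squared_error",
)


class ConvergenceError(RuntimeError):
    pass


class MultiTaskRidge(RegressorMixin, BaseEstimator):
    """L2-penalized multi-output linear regression without intercept.

    Parameters
    ----------
    alpha : float, default 0.01
        Regularization strength of the Frobenius penalty in the
        n-normalized objective (see module docstring).
    solver : {"closed_form", "coordinate_descent"}
        Closed form solves the normal equations; coordinate descent sweeps
        features cyclically in fixed order with full passes, stopping when
        the maximum absolute coefficient change falls below ``tol``.
    tol : float, default 1e-8
        Coordinate-descent convergence tolerance.
    max_iter : int, default 10_000
        Coordinate-descent pass cap; exceeding it raises ConvergenceError.

    Attributes
    ----------
    coef_ : ndarray of shape (p, k)
        The coefficient matrix W (features in rows, outcomes in columns).
    """

    def __init__(
        self,
        alpha: float = 0.01,
        solver: str = "closed_form",
        tol: float = 1e-8,
        max_iter: int = 10_000,
    ):
        self.alpha = alpha
        self.solver = solver
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.solver not in ("closed_form", "coordinate_descent"):
            raise ValueError(f"unknown solver {self.solver!r}")
        self.feature_names_in_ = (
            np.asarray(X.columns) if isinstance(X, pd.DataFrame) else None
        )
        self.outcome_names_ = (
            np.asarray(y.columns) if isinstance(y, pd.DataFrame) else None
        )
        X = np.asarray(X, dtype=float)
        Y = np.asarray(y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        if Y.shape[0] != n:
            raise ValueError("X and Y row counts differ")
        if self.solver == "closed_form":
            self.coef_ = _ridge_closed_form(X, Y, self.alpha)
            self.n_iter_ = 0
        else:
            self.coef_, self.n_iter_ = _ridge_coordinate_descent(
                X, Y, self.alpha, self.tol, self.max_iter
            )
        self.n_features_in_ = p
        return self

    def predict(self, X):
        W = self.coef_
        X = np.asarray(X, dtype=float)
        if X.shape[1] != W.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} columns but the model expects {W.shape[0]}"
            )
        return X @ W

    def coefficients(self) -> pd.DataFrame:
        """coef_ as a feature-by-indicator DataFrame when names are known."""
        idx = self.feature_names_in_
        cols = self.outcome_names_
        return pd.DataFrame(
            self.coef_,
            index=idx if idx is not None else None,
            columns=cols if cols is not None else None,
        )


def _ridge_closed_form(X: np.ndarray, Y: np.ndarray, alpha: float) -> np.ndarray:
    n, p = X.shape
    G = X.T @ X / n
    G[np.diag_indices_from(G)] += alpha
    return np.linalg.solve(G, X.T @ Y / n)


def _ridge_coordinate_descent(
    X: np.ndarray, Y: np.ndarray, alpha: float, tol: float, max_iter: int
) -> tuple[np.ndarray, int]:
    """Cyclic coordinate descent on the n-normalized ridge objective.

    Each coordinate update is exact:
        w_j <- (x_j' (Y - X W + x_j w_j) / n) / (x_j' x_j / n + alpha)
    updating all k outcome columns of row j at once.
    """
    n, p = X.shape
    k = Y.shape[1]
    W = np.zeros((p, k))
    g = (X * X).sum(axis=0) / n  # x_j'x_j / n
    R = Y.copy()  # residual Y - XW
    for sweep in range(1, max_iter + 1):
        max_change = 0.0
        for j in range(p):
            xj = X[:, j]
            rho = xj @ R / n + g[j] * W[j]
            w_new = rho / (g[j] + alpha)
            diff = w_new - W[j]
            change = np.abs(diff).max()
            if change > 0:
                R -= np.outer(xj, diff)
                W[j] = w_new
                max_change = max(max_change, change)
        if max_change < tol:
            return W, sweep
    raise ConvergenceError(
        f"coordinate descent did not converge in {max_iter} sweeps "
        f"(final max coefficient change {max_change:.3e})"
    )


# ---------------------------------------------------------------------------
# metrics


def metric_report(Y, Y_hat) -> pd.DataFrame:
    """Per-indicator and pooled prediction metrics.

    Rows are the outcome columns plus ``pooled`` (the unweighted mean over
    outcomes); columns are Pearson's r, explained variance score
    (1 - Var(Y - Yhat)/Var(Y)), mean absolute error, coefficient of
    determination (1 - SS_res/SS_tot) and mean squared error.  EVS and R2
    differ when predictions are mean-biased.
    """
    names = list(Y.columns) if isinstance(Y, pd.DataFrame) else None
    Y = np.asarray(Y, dtype=float)
    Y_hat = np.asarray(Y_hat, dtype=float)
    if Y.ndim == 1:
        Y, Y_hat = Y[:, None], Y_hat[:, None]
    if Y.shape != Y_hat.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {Y_hat.shape}")
    if names is None:
        names = [f"y{j}" for j in range(Y.shape[1])]
    if np.any(Y.std(axis=0) == 0):
        bad = [names[j] for j in np.flatnonzero(Y.std(axis=0) == 0)]
        raise ValueError(f"zero-variance outcome columns: {bad}")
    # Pearson r per column; a constant prediction has undefined r, scored 0
    yc = Y - Y.mean(axis=0)
    pc = Y_hat - Y_hat.mean(axis=0)
    denom = np.sqrt((yc**2).sum(axis=0) * (pc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (yc * pc).sum(axis=0) / denom, 0.0)
    rows = {
        "pearson_r": r,
        "explained_variance_score": explained_variance_score(
            Y, Y_hat, multioutput="raw_values"
        ),
        "mean_absolute_error": mean_absolute_error(Y, Y_hat, multioutput="raw_values"),
        "coefficient_of_determination": r2_score(Y, Y_hat, multioutput="raw_values"),
        "mean_squared_error": mean_squared_error(Y, Y_hat, multioutput="raw_values"),
    }
    report = pd.DataFrame(rows, index=names)
    report.loc["pooled"] = report.mean(axis=0)
    return report


# ---------------------------------------------------------------------------
# cross-validated benchmark harness

MODEL_REGISTRY: dict = {
    "ridge": lambda **kw: MultiTaskRidge(**kw),
    "ols": lambda **kw: LinearRegression(fit_intercept=False, **kw),
    "knn": lambda **kw: KNeighborsRegressor(**kw),
}


def crossval_benchmark(
    features: pd.DataFrame,
    ses: pd.DataFrame,
    nuisance: pd.DataFrame | None = None,
    covariates: pd.DataFrame | None = None,
    model: str = "ridge",
    model_params: dict | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-sample metric report for a registered learner.

    Standardization and confound residualization are learned on the training
    folds only and applied to the held-out fold; fold-wise metric reports are
    averaged.  The registry ships multitask ridge, ordinary least squares and
    a k-nearest-neighbor regressor; further learners are pluggable via
    :data:`MODEL_REGISTRY`.
    """
    if model not in MODEL_REGISTRY:
        raise KeyError(
            f"unknown model {model!r}; registered: {sorted(MODEL_REGISTRY)}"
        )
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    factory = MODEL_REGISTRY[model]
    params = model_params or {}
    X_all = features
    folds = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    reports = []
    for train, test in folds.split(X_all):
        X_tr, X_te = X_all.iloc[train], X_all.iloc[test]
        if nuisance is not None:
            resid = ConfoundResidualizer().fit(X_tr, nuisance.iloc[train])
            X_tr = resid.transform(X_tr, nuisance.iloc[train])
            X_te = resid.transform(X_te, nuisance.iloc[test])
        if covariates is not None:
            X_tr = pd.concat([X_tr, covariates.iloc[train]], axis=1)
            X_te = pd.concat([X_te, covariates.iloc[test]], axis=1)
        x_scale = ColumnStandardizer().fit(X_tr)
        y_scale = ColumnStandardizer().fit(ses.iloc[train])
        est = factory(**params)
        est.fit(x_scale.transform(X_tr), y_scale.transform(ses.iloc[train]))
        Y_hat = est.predict(x_scale.transform(X_te))
        reports.append(metric_report(y_scale.transform(ses.iloc[test]), Y_hat))
    mean = reports[0].copy()
    mean.loc[:, :] = np.mean([r.to_numpy() for r in reports], axis=0)
    return mean
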