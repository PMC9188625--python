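"""Descriptive structure of the six SES indicators.

Pairwise Pearson correlations, a principal-component mixture decomposition
of the indicator block, simple demographic associations (standardized
slopes on age or sex), and a principal-component regression that feeds
component scores through the multi-output ridge estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ColumnStandardizer
from .ridge import MultiTaskRidge

__all__ = [
    "PCAResult",
    "pairwise_correlation",
    "pca_decompose",
    "univariate_assoc",
    "pc_regression",
]


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # indicator x component
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame  # participant x component
    eigenvalues: np.ndarray


def pairwise_correlation(ses: pd.DataFrame) -> pd.DataFrame:
    """6x6 Pearson correlation matrix of the SES indicators."""
    arr = np.asarray(ses, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("pairwise_correlation requires complete cases")
    sds = arr.std(axis=0, ddof=1)
    if (sds <= 1e-12).any():
        bad = [str(ses.columns[j]) for j in np.flatnonzero(sds <= 1e-12)]
        raise ValueError(f"constant indicators: {bad}")
    return pd.DataFrame(np.corrcoef(arr, rowvar=False), index=ses.columns, columns=ses.columns)


def pca_decompose(ses: pd.DataFrame) -> PCAResult:
    """Eigendecomposition of the indicator correlation matrix.

    Because indicators are z-scored, PCA on the correlation matrix equals
    PCA on the covariance matrix; explained-variance ratios are the
    eigenvalues divided by k and therefore sum to one.  Component signs are
    fixed so each component's largest-magnitude loading is positive.
    """
    Z = ColumnStandardizer().fit_transform(ses)
    corr = pairwise_correlation(ses).to_numpy()
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if eigvals[0] <= 1e-12:
        raise ValueError("correlation matrix has collapsed rank")
    for j in range(eigvecs.shape[1]):
        if eigvecs[np.abs(eigvecs[:, j]).argmax(), j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    k = corr.shape[0]
    comp_names = [f"PC{j + 1}" for j in range(k)]
    loadings = pd.DataFrame(eigvecs, index=ses.columns, columns=comp_names)
    scores = pd.DataFrame(
        np.asarray(Z) @ eigvecs, index=ses.index, columns=comp_names
    )
    return PCAResult(
        loadings=loadings,
        explained_variance_ratio=eigvals / k,
        scores=scores,
        eigenvalues=eigvals,
    )


def univariate_assoc(ses: pd.DataFrame, covariate) -> pd.Series:
    """Standardized slope of each indicator on one demographic covariate.

    Both sides are z-scored, so the slope equals their Pearson correlation
    (the convention behind simple age/sex association tables).
    """
    cov = np.asarray(covariate, dtype=float)
    if cov.std(ddof=1) <= 1e-12:
        raise ValueError("constant covariate")
    zc = (cov - cov.mean()) / cov.std(ddof=1)
    out = {}
    for name in ses.columns:
        y = ses[name].to_numpy(dtype=float)
        if y.std(ddof=1) <= 1e-12:
            raise ValueError(f"constant indicator {name!r}")
        zy = (y - y.mean()) / y.std(ddof=1)
        out[name] = float(zc @ zy / (len(zc) - 1))
    return pd.Series(out)


def pc_regression(
    X: pd.DataFrame, scores: pd.DataFrame, alpha: float = 0.0
) -> pd.DataFrame:
    """Regress standardized principal-component scores on the design matrix.

    Delegates to :class:`MultiTaskRidge`; alpha = 0 is the classical
    linear-regression check applied to component scores.
    """
    Zs = ColumnStandardizer().fit_transform(scores)
    model = MultiTaskRidge(alpha=alpha).fit(X, Zs)
    return model.coefficients()
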