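"""Indicator orientation, confound residualization, covariates, z-scoring.

Produces the design matrix X (brain features plus an appended covariate
block) and the outcome matrix Y (six z-scored SES indicators).  The z-score
uses the sample (n-1) standard-deviation convention throughout.  This module
is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import INDICATORS

__all__ = [
    "OrientationMap",
    "default_orientation",
    "orient_indicators",
    "ConfoundResidualizer",
    "residualize",
    "build_covariates",
    "drop_constant_columns",
    "ColumnStandardizer",
    "standardize",
]


@dataclass(frozen=True)
class OrientationMap:
    """Per-indicator direction and encoding.

    After orientation a larger value means higher socioeconomic status for
    every indicator; ``invert`` flips the sign of the raw scale (used for
    deprivation-coded indicators such as the Townsend index).
    """

    direction: dict[str, str] = field(default_factory=dict)  # "as-is" | "invert"
    encoding: dict[str, str] = field(default_factory=dict)  # continuous|ordinal|binary

    def __post_init__(self) -> None:
        if set(self.direction) != set(INDICATORS):
            raise ValueError(f"orientation map must cover exactly {INDICATORS}")
        bad = {v for v in self.direction.values()} - {"as-is", "invert"}
        if bad:
            raise ValueError(f"unknown direction values: {sorted(bad)}")


def default_orientation() -> OrientationMap:
    """Standard orientation: invert the deprivation-coded neighborhood index."""
    direction = {name: "as-is" for name in INDICATORS}
    direction["neighborhood"] = "invert"
    encoding = {
        "education_years": "continuous",
        "degree": "ordinal",
        "income": "ordinal",
        "job": "binary",
        "vehicle_count": "ordinal",
        "neighborhood": "continuous",
    }
    return OrientationMap(direction=direction, encoding=encoding)


def orient_indicators(
    raw_ses: pd.DataFrame, mapping: OrientationMap | None = None
) -> pd.DataFrame:
    """Orient all six SES indicators so that larger = higher SES."""
    mapping = mapping or default_orientation()
    missing = set(INDICATORS) - set(raw_ses.columns)
    if missing:
        raise KeyError(f"missing SES indicators: {sorted(missing)}")
    unknown = set(raw_ses.columns) - set(INDICATORS)
    if unknown:
        raise KeyError(f"unknown SES indicators: {sorted(unknown)}")
    out = raw_ses.loc[:, list(INDICATORS)].copy()
    for name in INDICATORS:
        col = pd.to_numeric(out[name], errors="coerce")
        if col.isna().any():
            raise ValueError(f"non-numeric entries in indicator {name!r}")
        out[name] = -col if mapping.direction[name] == "invert" else col
    return out


class ConfoundResidualizer(TransformerMixin, BaseEstimator):
    """Remove variance linearly explained by nuisance variables.

    Fits per-feature least squares on the nuisance block (with intercept)
    and subtracts the fitted values; residual columns are orthogonal to
    every (centered) nuisance column.
    """

    def fit(self, X, nuisance):
        X = np.asarray(X, dtype=float)
        N = self._design(nuisance)
        if X.shape[0] != N.shape[0]:
            raise ValueError(
                f"row mismatch: {X.shape[0]} feature rows vs {N.shape[0]} nuisance rows"
            )
        rank = np.linalg.matrix_rank(N)
        if rank < N.shape[1]:
            raise ValueError(
                "rank-deficient nuisance block; offending columns: "
                f"{self._offending_columns(nuisance)}"
            )
        self.coef_, *_ = np.linalg.lstsq(N, X, rcond=None)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, nuisance):
        X_arr = np.asarray(X, dtype=float)
        N = self._design(nuisance)
        resid = X_arr - N @ self.coef_
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(resid, index=X.index, columns=X.columns)
        return resid

    def fit_transform(self, X, nuisance):
        return self.fit(X, nuisance).transform(X, nuisance)

    @staticmethod
    def _design(nuisance) -> np.ndarray:
        N = np.asarray(nuisance, dtype=float)
        if N.ndim == 1:
            N = N[:, None]
        return np.column_stack([np.ones(N.shape[0]), N])

    @staticmethod
    def _offending_columns(nuisance) -> list:
        names = (
            list(nuisance.columns)
            if isinstance(nuisance, pd.DataFrame)
            else list(range(np.asarray(nuisance).shape[1]))
        )
        N = np.asarray(nuisance, dtype=float)
        kept = [np.ones(N.shape[0])]
        bad = []
        for j, name in enumerate(names):
            trial = np.column_stack(kept + [N[:, j]])
            if np.linalg.matrix_rank(trial) < trial.shape[1]:
                bad.append(name)
            else:
                kept.append(N[:, j])
        return bad


def residualize(features, nuisance):
    """One-shot confound residualization (fit and transform on the same rows)."""
    return ConfoundResidualizer().fit_transform(features, nuisance)


def build_covariates(
    age, sex, iq, handedness=None, index: pd.Index | None = None
) -> pd.DataFrame:
    """Covariate block in fixed order: age, sex, age2, age_sex, age2_sex, iq[, handedness].

    Age is centered before powers and interactions are formed, which reduces
    collinearity among the polynomial terms without changing the fitted
    subspace.  Sex must be coded {0, 1}.
    """
    for name, v in (("age", age), ("sex", sex), ("iq", iq)):
        if v is None:
            raise ValueError(f"required covariate vector {name!r} is missing")
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    iq = np.asarray(iq, dtype=float)
    if not np.isin(sex, [0.0, 1.0]).all():
        raise ValueError("sex must be coded {0, 1}")
    a = age - age.mean()
    cols = {
        "age": a,
        "sex": sex,
        "age2": a**2,
        "age_sex": a * sex,
        "age2_sex": a**2 * sex,
        "iq": iq,
    }
    if handedness is not None:
        cols["handedness"] = np.asarray(handedness, dtype=float)
    return pd.DataFrame(cols, index=index)


def drop_constant_columns(
    df: pd.DataFrame, tol: float = 1e-12
) -> tuple[pd.DataFrame, list[str]]:
    """Drop (and report) columns with negligible variance, e.g. degenerate
    interaction terms when age is constant."""
    sds = df.std(ddof=1)
    dropped = sds.index[(sds.fillna(0.0) <= tol)].tolist()
    return df.drop(columns=dropped), dropped


class ColumnStandardizer(TransformerMixin, BaseEstimator):
    """Column-wise z-scoring with the sample (n-1) sd convention.

    Training means and sds are stored so held-out rows can be transformed
    with the training parameters, and can be serialized via ``params()``.
    """

    def __init__(self, tol: float = 1e-12):
        self.tol = tol

    def fit(self, X, y=None):
        arr = np.asarray(X, dtype=float)
        names = (
            list(X.columns) if isinstance(X, pd.DataFrame) else list(range(arr.shape[1]))
        )
        self.mean_ = arr.mean(axis=0)
        self.scale_ = arr.std(axis=0, ddof=1)
        constant = [n for n, s in zip(names, self.scale_) if not s > self.tol]
        if constant:
            raise ValueError(f"constant columns cannot be standardized: {constant}")
        self.columns_ = names
        return self

    def transform(self, X):
        arr = np.asarray(X, dtype=float)
        z = (arr - self.mean_) / self.scale_
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(z, index=X.index, columns=X.columns)
        return z

    def inverse_transform(self, X):
        arr = np.asarray(X, dtype=float)
        back = arr * self.scale_ + self.mean_
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(back, index=X.index, columns=X.columns)
        return back

    def params(self) -> dict:
        return {
            "columns": [str(c) for c in self.columns_],
            "mean": self.mean_.tolist(),
            "sd": self.scale_.tolist(),
            "sd_convention": "sample (ddof=1)",
        }


def standardize(X) -> tuple[pd.DataFrame | np.ndarray, ColumnStandardizer]:
    """Z-score columns; returns the transformed matrix and the fitted scaler."""
    scaler = ColumnStandardizer().fit(X)
    return scaler.transform(X), scaler


def build_design(
    features: pd.DataFrame, covariates: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the design matrix: brain features then the covariate block.

    Returns the combined matrix and a per-column role series
    ("brain_feature" or "covariate").
    """
    if covariates is None or covariates.shape[1] == 0:
        roles = pd.Series("brain_feature", index=features.columns)
        return features.copy(), roles
    if not features.index.equals(covariates.index):
        raise ValueError("features and covariates must share the participant index")
    design = pd.concat([features, covariates], axis=1)
    if design.columns.duplicated().any():
        raise ValueError("duplicate column names between features and covariates")
    roles = pd.Series(
        ["brain_feature"] * features.shape[1] + ["covariate"] * covariates.shape[1],
        index=design.columns,
    )
    return design, roles
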