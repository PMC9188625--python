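"""Meta-analytic functional profiling of coefficient maps.

Correlates a gray-matter coefficient map (one column per SES indicator)
with each term column of a region-by-term association matrix, such as a
parcellated Neurosynth export.  Variants restrict the correlation to one
hemisphere or isolate the variance unique to a single indicator by first
residualizing its map on the other five.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "validate_term_matrix",
    "profile_terms",
    "profile_by_hemisphere",
    "unique_profile",
]


def validate_term_matrix(terms: pd.DataFrame, atlas: pd.DataFrame | None = None) -> None:
    if terms.shape[1] < 1:
        raise ValueError("term matrix needs at least one term column")
    if terms.isna().any().any():
        raise ValueError("term matrix contains missing values")
    if atlas is not None:
        gray = set(
            atlas.loc[atlas["tissue"].isin(["cortical", "subcortical"]), "feature_id"]
        )
        extra = set(terms.index) - gray
        if extra:
            raise ValueError(f"term-matrix regions outside the gray-matter atlas: {sorted(extra)}")


def _align(weights: pd.DataFrame | pd.Series, terms: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    W = weights.to_frame() if isinstance(weights, pd.Series) else weights
    missing = [fid for fid in terms.index if fid not in W.index]
    if missing:
        raise KeyError(f"weight map missing regions: {missing}")
    if len(terms.index) < 3:
        raise ValueError("need at least 3 regions for term profiling")
    return W.loc[terms.index], terms


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    if y.std() == 0:
        raise ValueError("zero-variance term column")
    if x.std() == 0:
        raise ValueError("zero-variance weight map")
    return float(stats.pearsonr(x, y).statistic)


def profile_terms(
    weights: pd.DataFrame | pd.Series, terms: pd.DataFrame, mode: str = "full"
) -> pd.DataFrame:
    """Pearson correlation of each term column with each indicator map.

    Returns a term-by-indicator frame of correlations, with a ``mode``
    attribute recorded in ``DataFrame.attrs``.
    """
    W, T = _align(weights, terms)
    out = pd.DataFrame(index=T.columns, columns=W.columns, dtype=float)
    for term in T.columns:
        t = T[term].to_numpy(dtype=float)
        for ind in W.columns:
            out.at[term, ind] = _corr(W[ind].to_numpy(dtype=float), t)
    out.attrs["mode"] = mode
    return out


def profile_by_hemisphere(
    weights: pd.DataFrame | pd.Series,
    terms: pd.DataFrame,
    atlas: pd.DataFrame,
    hemisphere: str,
) -> pd.DataFrame:
    """Term profile restricted to regions of one hemisphere (L or R)."""
    if hemisphere not in ("L", "R"):
        raise ValueError("hemisphere must be 'L' or 'R'")
    keep = set(atlas.loc[atlas["hemisphere"] == hemisphere, "feature_id"])
    sub = terms.loc[[fid for fid in terms.index if fid in keep]]
    if len(sub) < 3:
        raise ValueError(f"fewer than 3 regions in hemisphere {hemisphere}")
    return profile_terms(weights, sub, mode=f"by_hemisphere:{hemisphere}")


def unique_profile(
    all_weight_maps: pd.DataFrame, terms: pd.DataFrame, indicator: str
) -> pd.DataFrame:
    """Term profile of one indicator's map after partialling out the other maps.

    The target column is residualized (least squares with intercept) on the
    remaining indicator maps across regions, so the profile reflects
    meta-analytic associations uniquely explained by that indicator.
    """
    if indicator not in all_weight_maps.columns:
        raise KeyError(f"unknown indicator {indicator!r}")
    W, T = _align(all_weight_maps, terms)
    y = W[indicator].to_numpy(dtype=float)
    others = W.drop(columns=[indicator]).to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(y)), others])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    if resid.std() <= 1e-12 * max(y.std(), 1.0):
        raise ValueError(
            f"map for {indicator!r} is (numerically) a linear combination of the "
            "other indicator maps; unique profile is degenerate"
        )
    resid_map = pd.Series(resid, index=T.index, name=indicator)
    out = profile_terms(resid_map, T, mode="unique")
    return out
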