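"""Bootstrap-bagged coefficient maps and permutation family-wise-error inference.

Bagging: the full standardized model is refit on B participant resamples
drawn with replacement (n-out-of-n); the ensemble mean, standard deviation,
and 5%/95% percentile bounds summarize each of the p x k coefficients.

Permutation testing: the rows of the outcome block are shuffled jointly
(all six indicators move together) while the brain-feature matrix is held
fixed, destroying only the participant-level brain-SES correspondence.  For
each of R permutations the model is refit and the maximum absolute
coefficient over all p x k cells is recorded; comparing the observed
(bagged) coefficients against this max-statistic null controls the
family-wise error over every tested parameter.  P-values use the add-one
convention (1 + count) / (1 + R), so they are never exactly zero and the
smallest attainable value at R = 1000 is 1/1001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ColumnStandardizer
from .ridge import _ridge_closed_form

__all__ = [
    "BootstrapEnsemble",
    "BaggedSolution",
    "PermutationNull",
    "SignificanceReport",
    "bootstrap_bag",
    "permutation_null",
    "fwe_pvalues",
]

logger = logging.getLogger(__name__)


@dataclass
class BootstrapEnsemble:
    draws: np.ndarray  # (B, p, k)
    B: int
    seed: int


@dataclass
class BaggedSolution:
    """Bootstrap summary of the coefficient matrix (all frames feature x indicator)."""

    mean: pd.DataFrame
    sd: pd.DataFrame
    lo5: pd.DataFrame
    hi95: pd.DataFrame


@dataclass
class PermutationNull:
    max_stats: np.ndarray  # (R,)
    R: int
    seed: int
    statistic_mode: str  # "plain_fit" | "bagged_fit"


@dataclass
class SignificanceReport:
    p_fwe: pd.DataFrame
    significant: pd.DataFrame
    threshold: float

    def table(self, bagged: BaggedSolution) -> pd.DataFrame:
        """Long-format report: one row per (feature, indicator) cell."""
        rows = []
        for ind in self.p_fwe.columns:
            rows.append(
                pd.DataFrame(
                    {
                        "feature_id": self.p_fwe.index,
                        "indicator": ind,
                        "bagged_mean": bagged.mean[ind].to_numpy(),
                        "sd": bagged.sd[ind].to_numpy(),
                        "lo5": bagged.lo5[ind].to_numpy(),
                        "hi95": bagged.hi95[ind].to_numpy(),
                        "p_fwe": self.p_fwe[ind].to_numpy(),
                        "significant": self.significant[ind].to_numpy(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _standardized_arrays(X, Y) -> tuple[np.ndarray, np.ndarray]:
    Xs = ColumnStandardizer().fit_transform(X)
    Ys = ColumnStandardizer().fit_transform(Y)
    return np.asarray(Xs, dtype=float), np.asarray(Ys, dtype=float)


def bootstrap_bag(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    alpha: float = 0.01,
    B: int = 100,
    seed: int = 0,
    max_redraws: int = 100,
) -> tuple[BootstrapEnsemble, BaggedSolution]:
    """Refit the standardized model on B with-replacement resamples.

    Each draw re-standardizes its resample (sample sd convention) before the
    closed-form ridge fit.  A degenerate resample in which some column is
    constant is redrawn and the event logged.
    """
    if B < 2:
        raise ValueError("B must be >= 2 to form intervals")
    feat_ids = list(X.columns) if isinstance(X, pd.DataFrame) else None
    ind_ids = list(Y.columns) if isinstance(Y, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    n, p = Xa.shape
    k = Ya.shape[1]
    rng = np.random.default_rng(seed)
    draws = np.empty((B, p, k))
    for b in range(B):
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, n, n)
            Xb, Yb = Xa[idx], Ya[idx]
            if (Xb.std(axis=0, ddof=1) > 1e-12).all() and (
                Yb.std(axis=0, ddof=1) > 1e-12
            ).all():
                break
            logger.warning("degenerate bootstrap resample redrawn (draw %d)", b)
        else:
            raise RuntimeError(f"could not draw a non-degenerate resample (draw {b})")
        Xb = (Xb - Xb.mean(axis=0)) / Xb.std(axis=0, ddof=1)
        Yb = (Yb - Yb.mean(axis=0)) / Yb.std(axis=0, ddof=1)
        draws[b] = _ridge_closed_form(Xb, Yb, alpha)

    def frame(values: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(values, index=feat_ids, columns=ind_ids)

    bagged = BaggedSolution(
        mean=frame(draws.mean(axis=0)),
        sd=frame(draws.std(axis=0, ddof=1)),
        lo5=frame(np.percentile(draws, 5, axis=0)),
        hi95=frame(np.percentile(draws, 95, axis=0)),
    )
    return BootstrapEnsemble(draws=draws, B=B, seed=seed), bagged


def permutation_null(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    alpha: float = 0.01,
    R: int = 1000,
    seed: int = 0,
    statistic_mode: str = "plain_fit",
    B_inner: int = 100,
) -> PermutationNull:
    """Max-statistic permutation null for the coefficient matrix.

    The brain-feature matrix is held constant; only outcome rows are
    permuted (jointly across the six indicators).  In ``plain_fit`` mode
    each permutation records the max |coefficient| of a single closed-form
    refit — since X is unchanged, the normal-equation factorization is
    reused across permutations.  ``bagged_fit`` nests a full B_inner-draw
    bagging inside every permutation (computationally heavy; provided for
    fidelity checks).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if statistic_mode not in ("plain_fit", "bagged_fit"):
        raise ValueError(f"unknown statistic_mode {statistic_mode!r}")
    Xs, Ys = _standardized_arrays(X, Y)
    n, p = Xs.shape
    rng = np.random.default_rng(seed)
    max_stats = np.empty(R)
    if statistic_mode == "plain_fit":
        G = Xs.T @ Xs / n
        G[np.diag_indices_from(G)] += alpha
        from scipy.linalg import cho_factor, cho_solve

        factor = cho_factor(G)
        Xt = Xs.T / n
        for r in range(R):
            perm = rng.permutation(n)
            W = cho_solve(factor, Xt @ Ys[perm])
            max_stats[r] = np.abs(W).max()
    else:
        Y_df = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(Y)
        for r in range(R):
            perm = rng.permutation(n)
            _, bagged = bootstrap_bag(
                X, Y_df.iloc[perm].set_axis(Y_df.index), alpha=alpha, B=B_inner,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            max_stats[r] = np.abs(bagged.mean.to_numpy()).max()
    return PermutationNull(max_stats=max_stats, R=R, seed=seed, statistic_mode=statistic_mode)


def fwe_pvalues(
    observed: pd.DataFrame | BaggedSolution,
    null: PermutationNull,
    threshold: float = 0.001,
) -> SignificanceReport:
    """Family-wise-error corrected p-values for every (feature, indicator) cell.

    p_fwe(cell) = (1 + #{r : max_stat_r >= |observed(cell)|}) / (1 + R),
    two-sided through the absolute value, with ties counted against
    significance.  The observed statistic is normally the bagged mean.
    """
    obs = observed.mean if isinstance(observed, BaggedSolution) else observed
    values = np.abs(np.asarray(obs, dtype=float))
    counts = (null.max_stats[:, None, None] >= values[None, :, :]).sum(axis=0)
    p = (1.0 + counts) / (1.0 + null.R)
    index = obs.index if isinstance(obs, pd.DataFrame) else None
    columns = obs.columns if isinstance(obs, pd.DataFrame) else None
    p_fwe = pd.DataFrame(p, index=index, columns=columns)
    return SignificanceReport(
        p_fwe=p_fwe, significant=p_fwe < threshold, threshold=threshold
    )
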