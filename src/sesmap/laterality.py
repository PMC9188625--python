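"""Hemispheric-asymmetry statistics on coefficient maps.

Two complementary views of lateralization:

1.  Sign counts — every significant (feature, indicator) association on a
    lateralized feature contributes one count to a 2x2 table of hemisphere
    (L/R) by association sign (+/-); a Pearson chi-squared test on that
    table asks whether positive associations are distributed differently
    across hemispheres.
2.  Homologue correlation — Pearson's r between the coefficient values of
    left-hemisphere features and their right-hemisphere homologues, per
    tissue subset and per indicator (or pooled across indicators), with an
    optional bootstrap-uncertainty adjustment (bagged mean / bootstrap sd).

Midline features never enter either statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inference import BaggedSolution, SignificanceReport

__all__ = [
    "HomologueMap",
    "SignCountTable",
    "ChiSquareResult",
    "HemisphereCorrelation",
    "pair_homologues",
    "sign_count_table",
    "chi_square_test",
    "chisq_sf",
    "homologue_correlation",
    "asymmetry_summary",
]

SUBSETS = ("all_regions", "cortical", "subcortical", "tracts", "all_features")


@dataclass
class HomologueMap:
    """Left/right feature pairing derived from the atlas."""

    pairs: list[tuple[str, str, str]]  # (left_id, right_id, homologue_id)
    midline: list[str]


@dataclass
class SignCountTable:
    """2x2 counts: rows hemisphere (L, R), columns sign (+, -)."""

    counts: np.ndarray  # shape (2, 2)
    subset: str = "all_features"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=["L", "R"], columns=["positive", "negative"]
        )

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    correction: str


@dataclass
class HemisphereCorrelation:
    subset: str
    indicator: str  # one of the 6 or "pooled"
    r: float
    n_pairs: int


def pair_homologues(atlas: pd.DataFrame) -> HomologueMap:
    """Build the L/R pairing from shared homologue ids; validate the atlas."""
    if atlas["feature_id"].duplicated().any():
        dup = atlas.loc[atlas["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValueError(f"duplicate feature ids: {dup}")
    lateral = atlas[atlas["homologue_id"].notna()]
    pairs = []
    for hid, grp in lateral.groupby("homologue_id", sort=True):
        if len(grp) != 2 or set(grp["hemisphere"]) != {"L", "R"}:
            raise ValueError(
                f"homologue_id {hid!r} must have exactly one L and one R member, "
                f"got hemispheres {grp['hemisphere'].tolist()}"
            )
        left = grp.loc[grp["hemisphere"] == "L", "feature_id"].item()
        right = grp.loc[grp["hemisphere"] == "R", "feature_id"].item()
        pairs.append((left, right, hid))
    midline = atlas.loc[atlas["hemisphere"] == "M", "feature_id"].tolist()
    stray = atlas[(atlas["hemisphere"] != "M") & atlas["homologue_id"].isna()]
    if not stray.empty:
        raise ValueError(
            f"lateralized features without homologue_id: {stray['feature_id'].tolist()}"
        )
    return HomologueMap(pairs=pairs, midline=midline)


def _subset_feature_ids(atlas: pd.DataFrame, subset: str) -> set[str]:
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}; choose from {SUBSETS}")
    if subset == "all_features":
        keep = atlas
    elif subset == "all_regions":
        keep = atlas[atlas["tissue"].isin(["cortical", "subcortical"])]
    elif subset == "tracts":
        keep = atlas[atlas["tissue"] == "tract"]
    else:
        keep = atlas[atlas["tissue"] == subset]
    return set(keep["feature_id"])


def sign_count_table(
    report: SignificanceReport,
    bagged: BaggedSolution,
    hmap: HomologueMap,
    atlas: pd.DataFrame,
    subset: str = "all_features",
) -> SignCountTable:
    """Count significant lateralized associations by hemisphere and sign.

    Each significant (feature, indicator) cell counts once; a feature
    significant for several indicators contributes several counts.
    """
    keep = _subset_feature_ids(atlas, subset)
    if not keep:
        raise ValueError(f"subset {subset!r} selects no features")
    hemi = dict()
    for left, right, _ in hmap.pairs:
        hemi[left], hemi[right] = "L", "R"
    counts = np.zeros((2, 2), dtype=int)
    sig = report.significant
    means = bagged.mean
    for fid in sig.index:
        side = hemi.get(fid)
        if side is None or fid not in keep:
            continue  # midline or out-of-subset feature
        row = 0 if side == "L" else 1
        for ind in sig.columns:
            if sig.at[fid, ind]:
                col = 0 if means.at[fid, ind] > 0 else 1
                counts[row, col] += 1
    return SignCountTable(counts=counts, subset=subset)


def chi_square_test(
    table: SignCountTable | np.ndarray, correction: str = "none"
) -> ChiSquareResult:
    """Pearson chi-squared test of independence on a 2x2 sign-count table.

    With ``correction="none"`` the statistic is n (ad - bc)^2 / (row and
    column margin product); ``"yates"`` applies the continuity correction.
    All four margins must be positive for the test to be defined.
    """
    counts = table.counts if isinstance(table, SignCountTable) else np.asarray(table)
    if counts.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    a, b = counts[0]
    c, d = counts[1]
    n = counts.sum()
    margins = np.array([a + b, c + d, a + c, b + d], dtype=float)
    if (margins == 0).any():
        raise ValueError(
            f"zero margin in sign-count table {counts.tolist()}: test undefined"
        )
    if correction == "none":
        num = n * (a * d - b * c) ** 2
    elif correction == "yates":
        num = n * max(abs(a * d - b * c) - n / 2, 0.0) ** 2
    else:
        raise ValueError(f"unknown correction {correction!r}")
    statistic = float(num / margins.prod())
    return ChiSquareResult(
        statistic=statistic, df=1, p=chisq_sf(statistic, 1), correction=correction
    )


def chisq_sf(statistic: float, df: int = 1) -> float:
    """Upper-tail probability of the chi-squared distribution."""
    if statistic < 0:
        raise ValueError("chi-squared statistic must be >= 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(statistic, df))


def homologue_correlation(
    values: pd.DataFrame,
    hmap: HomologueMap,
    atlas: pd.DataFrame,
    subset: str = "all_features",
    per_indicator: bool = False,
    sd: pd.DataFrame | None = None,
) -> list[HemisphereCorrelation]:
    """Pearson correlation of left vs right homologue coefficient values.

    ``values`` is a feature-by-indicator map (e.g. bagged means).  If ``sd``
    is given, values are divided by it first (the bootstrap-uncertainty-
    adjusted, z-like map).  Pooled mode concatenates the indicator columns
    into one long left/right vector; ``per_indicator=True`` returns one
    correlation per indicator instead.
    """
    keep = _subset_feature_ids(atlas, subset)
    pairs = [(l, r) for l, r, _ in hmap.pairs if l in keep and r in keep]
    if len(pairs) < 3:
        raise ValueError(
            f"subset {subset!r} has {len(pairs)} pairs; need >= 3 for a correlation"
        )
    vals = values if sd is None else values / sd
    left = vals.loc[[l for l, _ in pairs]].to_numpy(dtype=float)
    right = vals.loc[[r for _, r in pairs]].to_numpy(dtype=float)

    def corr(x: np.ndarray, y: np.ndarray) -> float:
        if x.std() == 0 or y.std() == 0:
            raise ValueError("zero-variance vector in homologue correlation")
        return float(stats.pearsonr(x, y).statistic)

    if per_indicator:
        return [
            HemisphereCorrelation(
                subset=subset,
                indicator=str(ind),
                r=corr(left[:, j], right[:, j]),
                n_pairs=len(pairs),
            )
            for j, ind in enumerate(vals.columns)
        ]
    return [
        HemisphereCorrelation(
            subset=subset,
            indicator="pooled",
            r=corr(left.ravel(order="F"), right.ravel(order="F")),
            n_pairs=len(pairs),
        )
    ]


def asymmetry_summary(
    report: SignificanceReport,
    bagged: BaggedSolution,
    atlas: pd.DataFrame,
    uncertainty_adjusted: bool = True,
) -> dict:
    """Full laterality grid: sign-count tests and homologue correlations.

    Chi-squared tests are reported for the gray-matter and tract subsets
    when their tables have positive margins; homologue correlations cover
    every subset with at least 3 pairs, pooled and per indicator.
    """
    hmap = pair_homologues(atlas)
    sd = bagged.sd if uncertainty_adjusted else None
    out: dict = {"sign_tests": {}, "homologue_correlations": []}
    for subset in ("all_regions", "tracts"):
        try:
            table = sign_count_table(report, bagged, hmap, atlas, subset)
            test = chi_square_test(table)
            out["sign_tests"][subset] = {
                "table": table.counts.tolist(),
                "statistic": test.statistic,
                "df": test.df,
                "p": test.p,
                "n_significant": table.total,
            }
        except ValueError as exc:
            out["sign_tests"][subset] = {"error": str(exc)}
    for subset in SUBSETS:
        for per_ind in (False, True):
            try:
                results = homologue_correlation(
                    bagged.mean, hmap, atlas, subset, per_indicator=per_ind, sd=sd
                )
            except ValueError:
                continue
            out["homologue_correlations"].extend(
                {
                    "subset": hc.subset,
                    "indicator": hc.indicator,
                    "r": hc.r,
                    "n_pairs": hc.n_pairs,
                }
                for hc in results
            )
    return out
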