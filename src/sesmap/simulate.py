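"""Synthetic cohorts with the statistical structure the brain-SES analysis assumes.

The generator emulates a population-imaging cohort: atlas-level brain
phenotypes (region gray-matter volumes and white-matter tract fractional
anisotropy) contaminated by head-size/BMI confounds, six socioeconomic
indicators sharing a single latent factor, and a planted coefficient
pattern in which a configurable fraction of left/right homologue pairs
carries mirrored-sign effects (positive left, negative right).  All ground
truth needed for parameter-recovery tests is returned alongside the data.

Generative model
----------------
Brain features (p columns):  ``X = Z + head_size * c_h + bmi * c_b`` where
``Z`` is i.i.d. standard normal and the confound loadings ``c_h, c_b`` are
drawn ``N(0, confound_effect_sd)`` per feature.

SES indicators (k = 6 columns), before ordinal binning and orientation::

    y_j = Z @ w_j + outcome_noise_sd * (lambda_j * g + ses_noise_sd_j * e_j)

with ``g`` the shared latent SES factor and ``e_j`` idiosyncratic noise,
both standard normal.  The brain signal enters through the confound-free
part ``Z`` so that, by default, head size and BMI have no direct path to
SES.  Under ``effect_scale = 0`` the indicators follow a pure single-factor
model whose pairwise Pearson correlations obey the closed form
``lambda_i lambda_j / sqrt((lambda_i^2 + s_i^2)(lambda_j^2 + s_j^2))``.
"""

from __future__ import annotations


import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "INDICATORS",
    "GeneratorConfig",
    "SyntheticTruth",
    "Cohort",
    "generate_cohort",
    "make_term_matrix",
    "read_cohort",
]

#: Canonical indicator order (higher value = higher SES after orientation).
INDICATORS = (
    "education_years",
    "degree",
    "income",
    "job",
    "vehicle_count",
    "neighborhood",
)

#: Default ordinal encodings: degree/income in 5 bands, vehicle count in 4,
#: job as a binary white-/blue-collar split; the rest continuous.
DEFAULT_ORDINAL_BINS = (0, 5, 5, 2, 4, 0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generator settings.

    Counts are per hemisphere for homologous pairs (a pair yields one L and
    one R feature).  ``asymmetry_fraction`` is the fraction of effect-carrying
    homologue pairs whose left/right coefficients are exact mirror images;
    ``effect_fraction`` is the fraction of pairs (and midline features)
    carrying any planted effect at all.
    """

    n_participants: int = 5000
    n_homologous_pairs_cortical: int = 20
    n_homologous_pairs_subcortical: int = 5
    n_midline_regions: int = 2
    n_homologous_pairs_tracts: int = 5
    n_midline_tracts: int = 0
    ses_loadings: tuple[float, ...] = (0.6, 0.6, 0.5, 0.5, 0.4, 0.4)
    ses_noise_sd: tuple[float, ...] | float = 1.0
    ordinal_bins: tuple[int, ...] = DEFAULT_ORDINAL_BINS
    effect_scale: float = 0.1
    effect_fraction: float = 0.5
    asymmetry_fraction: float = 0.5
    confound_effect_sd: float = 0.3
    confound_to_ses_sd: float = 0.0
    outcome_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_homologous_pairs_cortical,
            self.n_homologous_pairs_subcortical,
            self.n_midline_regions,
            self.n_homologous_pairs_tracts,
            self.n_midline_tracts,
        )
        if any(c < 0 for c in counts):
            raise ValueError("feature counts must be >= 0")
        if self.n_features < 1:
            raise ValueError("total feature count must be >= 1")
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not 0.0 <= self.asymmetry_fraction <= 1.0:
            raise ValueError("asymmetry_fraction must lie in [0, 1]")
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValueError("effect_fraction must lie in [0, 1]")
        if len(self.ses_loadings) != 6:
            raise ValueError("ses_loadings must have 6 entries")
        if len(self.ordinal_bins) != 6:
            raise ValueError("ordinal_bins must have 6 entries")

    @property
    def n_pairs(self) -> int:
        return (
            self.n_homologous_pairs_cortical
            + self.n_homologous_pairs_subcortical
            + self.n_homologous_pairs_tracts
        )

    @property
    def n_features(self) -> int:
        return 2 * self.n_pairs + self.n_midline_regions + self.n_midline_tracts

    @property
    def ses_noise_vector(self) -> np.ndarray:
        s = self.ses_noise_sd
        if np.isscalar(s):
            return np.full(6, float(s))
        return np.asarray(s, dtype=float)


@dataclass
class SyntheticTruth:
    """Ground truth planted in a generated cohort."""

    true_coefficients: pd.DataFrame  # feature x indicator
    confound_loadings: pd.DataFrame  # feature x (head_size, bmi)
    latent_loadings: np.ndarray  # 6-vector
    effect_pair_ids: list[str]
    asymmetric_pair_ids: list[str]
    effect_midline_ids: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_coefficients": {
                "index": list(self.true_coefficients.index),
                "columns": list(self.true_coefficients.columns),
                "values": self.true_coefficients.to_numpy().tolist(),
            },
            "confound_loadings": {
                "index": list(self.confound_loadings.index),
                "columns": list(self.confound_loadings.columns),
                "values": self.confound_loadings.to_numpy().tolist(),
            },
            "latent_loadings": self.latent_loadings.tolist(),
            "effect_pair_ids": self.effect_pair_ids,
            "asymmetric_pair_ids": self.asymmetric_pair_ids,
            "effect_midline_ids": self.effect_midline_ids,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())

        def frame(key: str) -> pd.DataFrame:
            return pd.DataFrame(
                d[key]["values"], index=d[key]["index"], columns=d[key]["columns"]
            )

        return cls(
            true_coefficients=frame("true_coefficients"),
            confound_loadings=frame("confound_loadings"),
            latent_loadings=np.asarray(d["latent_loadings"]),
            effect_pair_ids=d["effect_pair_ids"],
            asymmetric_pair_ids=d["asymmetric_pair_ids"],
            effect_midline_ids=d["effect_midline_ids"],
        )


@dataclass
class Cohort:
    """Participant-aligned brain-feature, SES, and confound tables plus atlas."""

    features: pd.DataFrame  # n x p, index participant_id
    ses: pd.DataFrame  # n x 6
    confounds: pd.DataFrame  # n x (head_size, bmi, age, sex, iq, handedness)
    atlas: pd.DataFrame  # p x (feature_id, name, hemisphere, tissue, homologue_id)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, df in (
            ("features", self.features),
            ("ses", self.ses),
            ("confounds", self.confounds),
        ):
            df.to_csv(directory / f"{name}.tsv", sep="\t", index_label="participant_id")
        self.atlas.to_csv(directory / "atlas.tsv", sep="\t", index=False)


def read_cohort(directory: str | Path) -> Cohort:
    directory = Path(directory)
    tables = {
        name: pd.read_csv(directory / f"{name}.tsv", sep="\t", index_col="participant_id")
        for name in ("features", "ses", "confounds")
    }
    atlas = pd.read_csv(directory / "atlas.tsv", sep="\t", keep_default_na=False)
    atlas["homologue_id"] = atlas["homologue_id"].replace("", np.nan)
    return Cohort(atlas=atlas, **tables)


# ---------------------------------------------------------------------------
# atlas construction


def _build_atlas(config: GeneratorConfig) -> pd.DataFrame:
    rows = []

    def add_pairs(count: int, prefix: str, tissue: str) -> None:
        for i in range(count):
            hid = f"{prefix}_pair_{i:03d}"
            for hemi in ("L", "R"):
                rows.append(
                    {
                        "feature_id": f"{prefix}_{hemi}_{i:03d}",
                        "name": f"{prefix} region {i} ({hemi})",
                        "hemisphere": hemi,
                        "tissue": tissue,
                        "homologue_id": hid,
                    }
                )

    def add_midline(count: int, prefix: str, tissue: str) -> None:
        for i in range(count):
            rows.append(
                {
                    "feature_id": f"{prefix}_M_{i:03d}",
                    "name": f"{prefix} midline {i}",
                    "hemisphere": "M",
                    "tissue": tissue,
                    "homologue_id": np.nan,
                }
            )

    add_pairs(config.n_homologous_pairs_cortical, "ctx", "cortical")
    add_pairs(config.n_homologous_pairs_subcortical, "sub", "subcortical")
    # midline gray matter emulates brainstem-like structures
    add_midline(config.n_midline_regions, "mid", "subcortical")
    add_pairs(config.n_homologous_pairs_tracts, "tract", "tract")
    add_midline(config.n_midline_tracts, "mtract", "tract")
    return pd.DataFrame(rows)


def _plant_coefficients(
    config: GeneratorConfig, atlas: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[str], list[str], list[str]]:
    """Draw the planted feature-by-indicator coefficient matrix.

    Mirrored pairs carry +effect_scale on every left cell and -effect_scale on
    every right cell.  Other effect pairs and effect midline features draw
    signs i.i.d. per (feature, indicator) cell so that, absent planted
    asymmetry, left and right significant-association sign counts are
    statistically independent.
    """
    feature_ids = atlas["feature_id"].tolist()
    W = pd.DataFrame(0.0, index=feature_ids, columns=list(INDICATORS))

    pair_ids = atlas.loc[atlas["homologue_id"].notna(), "homologue_id"].unique().tolist()
    n_effect_pairs = round(config.effect_fraction * len(pair_ids))
    effect_pairs = sorted(
        rng.choice(pair_ids, size=n_effect_pairs, replace=False).tolist()
    ) if n_effect_pairs else []
    n_mirror = round(config.asymmetry_fraction * len(effect_pairs))
    mirrored = sorted(
        rng.choice(effect_pairs, size=n_mirror, replace=False).tolist()
    ) if n_mirror else []
    mirrored_set = set(mirrored)

    by_pair = (
        atlas[atlas["homologue_id"].notna()]
        .set_index(["homologue_id", "hemisphere"])
        .sort_index()
    )
    for hid in effect_pairs:
        left = by_pair.loc[(hid, "L"), "feature_id"]
        right = by_pair.loc[(hid, "R"), "feature_id"]
        if hid in mirrored_set:
            W.loc[left] = config.effect_scale
            W.loc[right] = -config.effect_scale
        else:
            W.loc[left] = config.effect_scale * rng.choice([-1.0, 1.0], size=6)
            W.loc[right] = config.effect_scale * rng.choice([-1.0, 1.0], size=6)

    midline_ids = atlas.loc[atlas["hemisphere"] == "M", "feature_id"].tolist()
    n_effect_mid = round(config.effect_fraction * len(midline_ids))
    effect_mid = sorted(
        rng.choice(midline_ids, size=n_effect_mid, replace=False).tolist()
    ) if n_effect_mid else []
    for fid in effect_mid:
        W.loc[fid] = config.effect_scale * rng.choice([-1.0, 1.0], size=6)

    return W, effect_pairs, mirrored, effect_mid


# ---------------------------------------------------------------------------
# ordinal encodings


def _quantile_bin(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Map a continuous vector to integer band codes 0..n_bins-1 by quantiles.

    n_bins == 2 is a median split.  Rank correlation with the underlying
    continuous variable is preserved by construction.
    """
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="right").astype(float)


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[Cohort, SyntheticTruth, pd.DataFrame]:
    """Generate a cohort, its planted ground truth, and the atlas table.

    Returns
    -------
    cohort : Cohort
        Brain features, SES indicators (ordinal-binned where configured,
        with ``neighborhood`` emitted on the deprivation scale so that the
        standard orientation map must invert it, and ``job`` coded
        1 = knowledge worker / 0 = manual worker), and confounds
        (head_size, bmi, age, sex, iq, handedness).
    truth : SyntheticTruth
        Planted coefficients (on the oriented scale), confound loadings,
        latent loadings and effect/mirrored bookkeeping.
    atlas : pandas.DataFrame
        Feature metadata (feature_id, name, hemisphere, tissue, homologue_id).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    atlas = _build_atlas(config)
    p = len(atlas)

    W, effect_pairs, mirrored, effect_mid = _plant_coefficients(config, atlas, rng)

    # confounds: simple, documented distributions
    head_size = rng.normal(0.0, 1.0, n)
    bmi = rng.normal(0.0, 1.0, n)
    age = rng.uniform(40.0, 70.0, n)
    sex = rng.integers(0, 2, n).astype(float)
    iq = rng.normal(0.0, 1.0, n)
    handedness = (rng.random(n) < 0.9).astype(float)  # 1 = right-handed

    c_h = rng.normal(0.0, config.confound_effect_sd, p)
    c_b = rng.normal(0.0, config.confound_effect_sd, p)
    Z = rng.normal(0.0, 1.0, (n, p))
    X = Z + np.outer(head_size, c_h) + np.outer(bmi, c_b)

    lam = np.asarray(config.ses_loadings, dtype=float)
    sig = config.ses_noise_vector
    g = rng.normal(0.0, 1.0, n)
    eps = rng.normal(0.0, 1.0, (n, 6))
    Y = Z @ W.to_numpy() + config.outcome_noise_sd * (np.outer(g, lam) + eps * sig)
    if config.confound_to_ses_sd > 0:
        gamma_h = rng.normal(0.0, config.confound_to_ses_sd, 6)
        gamma_b = rng.normal(0.0, config.confound_to_ses_sd, 6)
        Y = Y + np.outer(head_size, gamma_h) + np.outer(bmi, gamma_b)

    ses = pd.DataFrame(Y, columns=list(INDICATORS))
    for j, (name, bins) in enumerate(zip(INDICATORS, config.ordinal_bins)):
        if bins >= 2:
            ses[name] = _quantile_bin(ses[name].to_numpy(), bins)
    # neighborhood is emitted Townsend-style (higher = more deprived); the
    # preprocessing orientation map must invert it back.
    ses["neighborhood"] = -ses["neighborhood"]

    pid = pd.Index([f"sub-{i:06d}" for i in range(n)], name="participant_id")
    cohort = Cohort(
        features=pd.DataFrame(X, index=pid, columns=atlas["feature_id"].tolist()),
        ses=ses.set_index(pid),
        confounds=pd.DataFrame(
            {
                "head_size": head_size,
                "bmi": bmi,
                "age": age,
                "sex": sex,
                "iq": iq,
                "handedness": handedness,
            },
            index=pid,
        ),
        atlas=atlas,
    )
    truth = SyntheticTruth(
        true_coefficients=W,
        confound_loadings=pd.DataFrame(
            {"head_size": c_h, "bmi": c_b}, index=atlas["feature_id"].tolist()
        ),
        latent_loadings=lam,
        effect_pair_ids=effect_pairs,
        asymmetric_pair_ids=mirrored,
        effect_midline_ids=effect_mid,
    )
    return cohort, truth, atlas


def make_term_matrix(
    atlas: pd.DataFrame,
    n_terms: int,
    seed: int,
    collinear_with: pd.Series | None = None,
) -> pd.DataFrame:
    """Region-by-term association fixture restricted to gray-matter features.

    Values lie in [0, 1].  If ``collinear_with`` is given (a coefficient map
    indexed by feature_id), the first term column is an affine rescaling of
    that map into [0, 1] so its Pearson correlation with the map is exactly 1;
    remaining columns are uniform random.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    gray = atlas.loc[atlas["tissue"].isin(["cortical", "subcortical"]), "feature_id"]
    if gray.empty:
        raise ValueError("atlas has no gray-matter (cortical/subcortical) features")
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.0, 1.0, (len(gray), n_terms))
    labels = [f"term_{i:03d}" for i in range(n_terms)]
    terms = pd.DataFrame(values, index=pd.Index(gray, name="feature_id"), columns=labels)
    if collinear_with is not None:
        v = collinear_with.reindex(gray).to_numpy(dtype=float)
        span = v.max() - v.min()
        if span <= 0:
            raise ValueError("collinear_with map is constant over gray-matter features")
        terms.iloc[:, 0] = (v - v.min()) / span
        terms = terms.rename(columns={labels[0]: "term_planted"})
    return terms
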