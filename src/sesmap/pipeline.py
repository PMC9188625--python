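"""End-to-end orchestration: simulate/load -> preprocess -> fit -> infer ->
laterality -> structure -> annotate, with all stage outputs written under a
run directory and a single JSON summary.

Stage order mirrors the analysis workflow: deconfound brain features on
head size and BMI, build and z-score the design, fit the multi-output
ridge, bag it over bootstrap resamples, derive the permutation
max-statistic null, then compute laterality, SES-structure and annotation
summaries from the fitted objects.  Reruns with an identical config and
seed reproduce byte-identical tabular outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, laterality, structure
from .inference import bootstrap_bag, fwe_pvalues, permutation_null
from .preprocess import (
    ColumnStandardizer,
    build_covariates,
    build_design,
    default_orientation,
    drop_constant_columns,
    orient_indicators,
    residualize,
)
from .ridge import MultiTaskRidge
from .simulate import GeneratorConfig, generate_cohort, make_term_matrix, read_cohort

__all__ = ["PipelineConfig", "run_pipeline", "SchemaError"]


class SchemaError(ValueError):
    """Input tables do not conform to the expected schemas."""


@dataclass
class PipelineConfig:
    """Fully serializable run configuration.

    Either ``cohort_dir`` points at TSV inputs (features/ses/confounds/atlas)
    or ``generator`` settings are used to simulate a cohort.
    """

    cohort_dir: str | None = None
    generator: dict = field(default_factory=dict)
    alpha: float = 0.01
    solver: str = "closed_form"
    B: int = 100
    R: int = 1000
    threshold: float = 0.001
    statistic_mode: str = "plain_fit"
    include_covariates: bool = True
    include_handedness: bool = False
    uncertainty_adjusted: bool = True
    n_terms: int = 0  # 0 disables annotation unless a term matrix is supplied
    term_matrix: str | None = None
    seed: int = 0
    output_dir: str = "sesmap_run"

    def validate(self) -> None:
        if self.B < 2:
            raise SchemaError("B must be >= 2")
        if self.R < 1:
            raise SchemaError("R must be >= 1")
        if not 0 < self.threshold <= 1:
            raise SchemaError("threshold must lie in (0, 1]")
        if self.alpha < 0:
            raise SchemaError("alpha must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        canon = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    if config.cohort_dir is not None:
        cohort = read_cohort(config.cohort_dir)
        truth = None
    else:
        gen = GeneratorConfig(**{**config.generator, "seed": config.seed})
        cohort, truth, _ = generate_cohort(gen)
    required = {"head_size", "bmi", "age", "sex", "iq"}
    missing = required - set(cohort.confounds.columns)
    if missing:
        raise SchemaError(f"confound table missing columns: {sorted(missing)}")
    atlas_cols = {"feature_id", "name", "hemisphere", "tissue", "homologue_id"}
    if not atlas_cols <= set(cohort.atlas.columns):
        raise SchemaError(
            f"atlas table missing columns: {sorted(atlas_cols - set(cohort.atlas.columns))}"
        )
    if list(cohort.features.columns) != cohort.atlas["feature_id"].tolist():
        raise SchemaError("feature columns must match atlas feature_id order")
    for name, df in (("features", cohort.features), ("ses", cohort.ses)):
        if df.isna().any().any():
            raise SchemaError(f"{name} table contains missing values")
    return cohort, truth


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> dict:
    """Execute every stage; write stage outputs and return the summary dict."""
    config.validate()
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    summary: dict = {"config_hash": config.hash(), "seed": config.seed}

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, *exc):
                timings[name] = round(time.perf_counter() - self_inner.t0, 4)

        return _Timer()

    with stage("load"):
        cohort, truth = _load_inputs(config)
        cohort.write(outdir / "cohort")
        if truth is not None:
            truth.to_json(outdir / "cohort" / "truth.json")

    with stage("preprocess"):
        ses = orient_indicators(cohort.ses, default_orientation())
        feats = residualize(cohort.features, cohort.confounds[["head_size", "bmi"]])
        if config.include_covariates:
            cov = build_covariates(
                cohort.confounds["age"],
                cohort.confounds["sex"],
                cohort.confounds["iq"],
                handedness=(
                    cohort.confounds["handedness"]
                    if config.include_handedness and "handedness" in cohort.confounds
                    else None
                ),
                index=cohort.features.index,
            )
            cov, dropped = drop_constant_columns(cov)
        else:
            cov, dropped = None, []
        design, roles = build_design(feats, cov)
        x_scaler = ColumnStandardizer().fit(design)
        y_scaler = ColumnStandardizer().fit(ses)
        X = x_scaler.transform(design)
        Y = y_scaler.transform(ses)
        (outdir / "standardization.json").write_text(
            json.dumps({"X": x_scaler.params(), "Y": y_scaler.params()}, indent=1)
        )
        summary["n_participants"] = int(X.shape[0])
        summary["p"] = int(X.shape[1])
        summary["dropped_covariates"] = dropped

    with stage("fit"):
        model = MultiTaskRidge(alpha=config.alpha, solver=config.solver).fit(X, Y)
        W = model.coefficients()
        W.to_csv(outdir / "coefficients.tsv", sep="\t", index_label="feature_id")

    with stage("bag"):
        _, bagged = bootstrap_bag(
            design, ses, alpha=config.alpha, B=config.B, seed=config.seed
        )
        bagged.mean.to_csv(outdir / "bagged_mean.tsv", sep="\t", index_label="feature_id")

    with stage("permute"):
        null = permutation_null(
            design,
            ses,
            alpha=config.alpha,
            R=config.R,
            seed=config.seed + 1,
            statistic_mode=config.statistic_mode,
        )
        report = fwe_pvalues(bagged, null, threshold=config.threshold)
        report.table(bagged).to_csv(outdir / "significance.tsv", sep="\t", index=False)
        summary["n_significant"] = int(report.significant.to_numpy().sum())

    with stage("laterality"):
        brain_ids = roles.index[roles == "brain_feature"]
        lat = laterality.asymmetry_summary(
            _restrict(report, brain_ids),
            _restrict_bagged(bagged, brain_ids),
            cohort.atlas,
            uncertainty_adjusted=config.uncertainty_adjusted,
        )
        (outdir / "laterality.json").write_text(json.dumps(lat, indent=1))
        summary["laterality"] = lat

    with stage("structure"):
        corr = structure.pairwise_correlation(ses)
        pca = structure.pca_decompose(ses)
        corr.to_csv(outdir / "ses_correlation.tsv", sep="\t")
        struct = {
            "max_abs_offdiag_correlation": float(
                np.abs(corr.to_numpy() - np.eye(6)).max()
            ),
            "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
            "univariate_age": structure.univariate_assoc(
                ses, cohort.confounds["age"]
            ).to_dict(),
            "univariate_sex": structure.univariate_assoc(
                ses, cohort.confounds["sex"]
            ).to_dict(),
        }
        (outdir / "structure.json").write_text(json.dumps(struct, indent=1))
        summary["structure"] = struct

    with stage("annotate"):
        terms = None
        if config.term_matrix is not None:
            terms = pd.read_csv(config.term_matrix, sep="\t", index_col="feature_id")
        elif config.n_terms > 0:
            terms = make_term_matrix(cohort.atlas, config.n_terms, seed=config.seed + 2)
        if terms is not None:
            annotation.validate_term_matrix(terms, cohort.atlas)
            gray_map = bagged.mean.loc[[f for f in terms.index]]
            prof = annotation.profile_terms(gray_map, terms)
            prof.to_csv(outdir / "term_profile.tsv", sep="\t", index_label="term")
            summary["n_terms_profiled"] = int(prof.shape[0])

    summary["timings_s"] = timings
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "stage_wall_time_s": timings,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return summary


def _restrict(report, feature_ids):
    from .inference import SignificanceReport

    return SignificanceReport(
        p_fwe=report.p_fwe.loc[feature_ids],
        significant=report.significant.loc[feature_ids],
        threshold=report.threshold,
    )


def _restrict_bagged(bagged, feature_ids):
    from .inference import BaggedSolution

    return BaggedSolution(
        mean=bagged.mean.loc[feature_ids],
        sd=bagged.sd.loc[feature_ids],
        lo5=bagged.lo5.loc[feature_ids],
        hi95=bagged.hi95.loc[feature_ids],
    )
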