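"""End-to-end pipeline: split -> preprocess -> select -> train -> fuse -> evaluate.

``run_pipeline`` executes the full framework on one cohort and writes every
artifact (preprocess report, stepwise trace, metric matrix, fusion weights,
evaluation report, reproducibility manifest) into a run directory.  All
randomness is governed by the seeds recorded in the manifest; two runs with
an identical config produce byte-identical weight JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tcf import __version__
from tcf.cohort import CohortTable, read_cohort, write_schema
from tcf.derived import add_derived_features
from tcf.ensemble import default_model_specs, fit_ensemble, predict_matrix, split_cohort
from tcf.evaluate import (
    aggregate_importance,
    bootstrap_ci,
    calibration_curve,
    decision_curve,
    extract_importances,
    metric_matrix,
    score_metrics,
)
from tcf.fusion import METRIC_NAMES, classify, compute_weights, fuse_probabilities
from tcf.preprocess import (
    PreprocessReport,
    apply_minmax,
    filter_boolean_variance,
    filter_correlation,
    filter_missing_rate,
    fit_minmax,
    imputation_tournament,
    impute_table,
    smote_oversample,
)
from tcf.selection import rank_features, stepwise_select

log = logging.getLogger("tcf")


@dataclass
class RunConfig:
    """Every threshold, seed and toggle of the pipeline."""

    out_dir: str = "tcf_run"
    cohort_csv: str | None = None
    schema_file: str | None = None
    add_derived: bool = False
    train_fraction: float = 0.8
    stratified: bool = True
    missing_threshold: float = 0.30
    agreement_threshold: float = 0.90
    r_threshold: float = 0.7
    smote_ratio: float = 1.0
    k_neighbors: int = 5
    entropy_bins: int = 10
    ranking_direction: str = "low_entropy_first"
    n_search_iterations: int = 50
    n_folds: int = 5
    fuse: bool = True
    n_bootstrap: int = 1000
    threshold: float = 0.5
    seed: int = 0

    def content_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunResult:
    """In-memory view of a pipeline run's main artifacts."""

    config: RunConfig
    report: PreprocessReport
    selected_features: list[str]
    weights: object | None
    metric_frame: pd.DataFrame
    fused_metrics: dict | None
    out_dir: Path


def run_pipeline(config: RunConfig, cohort: CohortTable | None = None) -> RunResult:
    """Run the full framework; see the module docstring for the stage order."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        if not config.cohort_csv or not config.schema_file:
            raise ValueError("either pass a cohort or set cohort_csv and schema_file")
        cohort = read_cohort(config.cohort_csv, config.schema_file)
    if config.add_derived:
        cohort = add_derived_features(cohort)

    train, validation = split_cohort(
        cohort, config.train_fraction, config.stratified, config.seed
    )
    log.info("split: %d train / %d validation", train.n_patients, validation.n_patients)

    # filtering cascade (fitted on training data, applied to both splits)
    report = PreprocessReport()
    train, stage = filter_missing_rate(train, config.missing_threshold)
    report.add(stage)
    train, stage = filter_boolean_variance(train, config.agreement_threshold)
    report.add(stage)
    train, stage = filter_correlation(train, config.r_threshold)
    report.add(stage)
    validation = validation.select_features(train.feature_names)

    # imputation tournament on the training split; winner imputes both splits
    (imp_name, imputer), tour_report = imputation_tournament(train, seed=config.seed)
    report.imputer_choice = imp_name
    report.tournament_aucs = tour_report.tournament_aucs
    log.info("imputation tournament: %s (AUCs %s)", imp_name, tour_report.tournament_aucs)
    train = impute_table(train, imputer)
    validation = impute_table(validation, imputer)

    # entropy-ranked stepwise selection against the validation split
    ranking = rank_features(train, config.ranking_direction, config.entropy_bins)
    trace = stepwise_select(train, validation, ranking, seed=config.seed)
    train = train.select_features(trace.chosen_features)
    validation = validation.select_features(trace.chosen_features)
    log.info("selected %d features", len(trace.chosen_features))

    # class balancing and scaling
    train = smote_oversample(train, config.smote_ratio, config.k_neighbors, config.seed)
    scaler = fit_minmax(train)
    train = apply_minmax(train, scaler)
    validation = apply_minmax(validation, scaler)

    # seven base learners
    specs = default_model_specs(config.seed, config.n_search_iterations)
    models = fit_ensemble(train, specs, config.n_folds)
    preds = predict_matrix(models, validation)
    mm = metric_matrix(preds, validation.y.to_numpy(), config.threshold)
    metric_frame = mm.to_frame()

    weights = None
    fused_metrics = None
    if config.fuse:
        weights = compute_weights(mm)
        fused = fuse_probabilities(preds, weights)
        fused_metrics = score_metrics(validation.y.to_numpy(), fused.fused, config.threshold)
        metric_frame.loc["TCF"] = [fused_metrics[m] for m in METRIC_NAMES]

    _write_artifacts(
        out, config, cohort, report, trace, metric_frame, weights, models,
        preds, validation,
    )
    return RunResult(
        config, report, trace.chosen_features, weights, metric_frame, fused_metrics, out
    )


def _write_artifacts(
    out, config, cohort, report, trace, metric_frame, weights, models, preds, validation
):
    report.to_json(out / "preprocess_report.json")
    trace.to_frame().to_csv(out / "stepwise_trace.csv", index=False)
    metric_frame.to_csv(out / "metric_matrix.csv")
    y_val = validation.y.to_numpy()
    pred_frame = pd.DataFrame(preds.proba.T, columns=list(preds.model_names))
    if weights is not None:
        (out / "fusion_weights.json").write_text(
            json.dumps(
                {
                    "alpha": weights.as_dict(),
                    "orientation": weights.orientation,
                    "closeness": [float(c) for c in weights.workspace.closeness],
                },
                indent=2,
                sort_keys=True,
            )
        )
        fused = fuse_probabilities(preds, weights)
        pred_frame["TCF"] = fused.fused
        pred_frame["label"] = classify(fused, config.threshold)
        calibration_curve(y_val, fused.fused).to_csv(out / "calibration.csv", index=False)
        decision_curve(y_val, fused.fused, np.arange(0.05, 0.96, 0.05)).to_csv(
            out / "decision_curve.csv", index=False
        )
        imps = extract_importances(models, validation.feature_names)
        aggregate_importance(imps, weights).to_csv(out / "importance.csv")
        ci = bootstrap_ci(y_val, fused.fused, "auc", config.n_bootstrap, seed=config.seed)
        (out / "fused_auc_ci.json").write_text(
            json.dumps(
                {"auc": ci.point, "lower": ci.lower, "upper": ci.upper, "n_resamples": ci.n_resamples},
                indent=2,
            )
        )
    pred_frame["outcome"] = y_val
    pred_frame.to_csv(out / "predictions.csv", index=False)
    write_schema(validation.specs, out / "selected_schema.yaml")
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "n_patients": cohort.n_patients,
        "prevalence": cohort.prevalence,
        "selected_features": trace.chosen_features,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    return RunConfig(**(yaml.safe_load(Path(path).read_text()) or {}))
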