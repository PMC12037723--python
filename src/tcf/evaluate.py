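"""Scoring, bootstrap confidence intervals, calibration, decision curves,
and fusion-weighted feature-importance aggregation.

Six metrics drive the whole framework: AUC (rank statistic, ties counted
half), F1, accuracy, precision, sensitivity and specificity, all at the 0.5
decision threshold unless stated otherwise.  Confidence intervals are
percentile bootstrap over patient-level resamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from tcf.fusion import METRIC_NAMES, FusionWeights, MetricMatrix, PredictionSet

#: families whose fitted models expose feature importances
TREE_FAMILIES = ("DT", "RF", "XGB", "LGBM", "GBDT")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(
    labels: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    y = np.asarray(labels).astype(int)
    pred = (np.asarray(probabilities, dtype=float) >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )


def score_metrics(
    labels: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """The six metrics as {auc, f1, acc, pre, sen, spe}.

    AUC is the Mann-Whitney statistic of the probabilities against the
    labels (ties count one half); the rest derive from the confusion counts
    at ``threshold``.  Precision with an empty predicted-positive set is 0
    (warned).  Both classes must be present.
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0,1]")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: only one class present")
    c = confusion_counts(y, p, threshold)
    sen = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    spe = c.tn / (c.tn + c.fp) if c.tn + c.fp else 0.0
    if c.tp + c.fp == 0:
        warnings.warn("no predicted positives; precision defined as 0", stacklevel=2)
        pre = 0.0
    else:
        pre = c.tp / (c.tp + c.fp)
    acc = (c.tp + c.tn) / c.n
    f1 = 2 * pre * sen / (pre + sen) if pre + sen else 0.0
    return {
        "auc": float(roc_auc_score(y, p)),
        "f1": float(f1),
        "acc": float(acc),
        "pre": float(pre),
        "sen": float(sen),
        "spe": float(spe),
    }


def metric_matrix(preds: PredictionSet, labels: np.ndarray, threshold: float = 0.5) -> MetricMatrix:
    """Score every sub-model on one dataset -> 7x6 matrix in canonical order."""
    rows = [
        [score_metrics(labels, preds.proba[i], threshold)[m] for m in METRIC_NAMES]
        for i in range(preds.proba.shape[0])
    ]
    return MetricMatrix(np.asarray(rows), preds.model_names)


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapCI:
    point: float
    lower: float
    upper: float
    n_resamples: int
    seed: int

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


def bootstrap_ci(
    labels: np.ndarray,
    probabilities: np.ndarray,
    metric: str | Callable[[np.ndarray, np.ndarray], float] = "auc",
    n_resamples: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    max_redraws: int = 100,
) -> BootstrapCI:
    """Percentile bootstrap CI over patient-level resamples with replacement.

    ``metric`` is one of the six metric names or a callable
    ``(labels, probabilities) -> float``.  Resamples lacking a class (or on
    which the metric raises) are redrawn up to ``max_redraws`` times each;
    if more than half the resamples fail the interval is an error.
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least two observations")
    if callable(metric):
        fn = metric
    else:
        name = metric
        fn = lambda yy, pp: score_metrics(yy, pp)[name]  # noqa: E731
    point = fn(y, p)
    rng = np.random.default_rng(seed)
    stats, failures = [], 0
    for _ in range(n_resamples):
        value = None
        for _attempt in range(max_redraws):
            idx = rng.integers(0, len(y), size=len(y))
            try:
                value = fn(y[idx], p[idx])
                break
            except Exception:
                continue
        if value is None:
            failures += 1
        else:
            stats.append(value)
    if failures > n_resamples / 2:
        raise RuntimeError(f"metric failed on {failures}/{n_resamples} resamples")
    lo, hi = np.percentile(stats, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return BootstrapCI(float(point), float(lo), float(hi), n_resamples, seed)


# ---------------------------------------------------------------------------
# calibration and decision curves


def calibration_curve(
    labels: np.ndarray, probabilities: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Reliability table: equal-width bins on [0,1], empty bins omitted.

    Columns: mean_predicted, observed_rate, n.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    edges = np.linspace(0, 1, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        rows.append(
            {
                "mean_predicted": float(p[mask].mean()),
                "observed_rate": float(y[mask].mean()),
                "n": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def decision_curve(
    labels: np.ndarray, probabilities: np.ndarray, thresholds: Sequence[float]
) -> pd.DataFrame:
    """Net benefit of the model vs treat-all and treat-none strategies.

    NB_model(t) = TP(t)/n - FP(t)/n * t/(1-t) with positives at p >= t;
    NB_all(t) = prevalence - (1-prevalence) * t/(1-t); NB_none = 0.
    """
    t = np.asarray(thresholds, dtype=float)
    if ((t <= 0) | (t >= 1)).any():
        raise ValueError("thresholds must lie strictly inside (0,1)")
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    n = len(y)
    prev = y.mean()
    rows = []
    for ti in t:
        c = confusion_counts(y, p, ti)
        odds = ti / (1 - ti)
        rows.append(
            {
                "threshold": float(ti),
                "nb_model": c.tp / n - c.fp / n * odds,
                "nb_all": prev - (1 - prev) * odds,
                "nb_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# importance aggregation


def extract_importances(models: Mapping[str, object], feature_names: Sequence[str]) -> pd.DataFrame:
    """Native feature importances of the five tree families, each summing to 1.

    SVM and NB are excluded by construction: a maximum-margin hyperplane and
    a conditional-independence density model do not yield per-feature
    importance weights.
    """
    cols = {}
    for family in TREE_FAMILIES:
        model = models[family]
        imp = np.asarray(getattr(model, "feature_importances_"), dtype=float)
        if len(imp) != len(feature_names):
            raise ValueError(f"{family}: importance length mismatch")
        total = imp.sum()
        cols[family] = imp / total if total > 0 else np.full_like(imp, 1 / len(imp))
    return pd.DataFrame(cols, index=list(feature_names))


def aggregate_importance(
    importances: pd.DataFrame, weights: FusionWeights
) -> pd.DataFrame:
    """Fusion-weighted importance over the tree families, renormalised.

    ``importances`` has one column per tree family (each summing to 1).  The
    aggregate is sum_i alpha_i * importance_i per feature, using the raw
    alpha of each tree family (SVM/NB alphas are simply unused), then
    renormalised to sum 1.  Returns the per-model columns plus 'aggregated',
    sorted by aggregated importance.
    """
    if set(importances.columns) != set(TREE_FAMILIES):
        raise ValueError(f"expected importance columns {TREE_FAMILIES}")
    alpha = weights.as_dict()
    agg = sum(alpha[f] * importances[f] for f in TREE_FAMILIES)
    out = importances.copy()
    out["aggregated"] = agg / agg.sum()
    return out.sort_values("aggregated", ascending=False)
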