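"""TOPSIS-based classification fusion: the core of the package.

Each of the seven base classifiers is treated as an alternative in a
multi-criteria decision problem whose six criteria are its validation
metrics (AUC, F1, ACC, PRE, SEN, SPE).  TOPSIS ranks the alternatives by
relative closeness to a positive ideal solution (PIS, the coordinate-wise
best) versus a negative ideal solution (NIS, the coordinate-wise worst) in
a column-normalised, index-weighted criteria space:

    z_ij  = x_ij / ||x_.j||_2                (vector normalisation)
    v_ij  = w_j z_ij,  w_j = 1/6             (equal index weights)
    d_i+  = || v_i - PIS ||_2,   d_i- = || v_i - NIS ||_2
    C_i   = d_i- / (d_i- + d_i+)             (closeness, in [0,1])
    alpha_i = C_i / sum_k C_k                (fusion weights)

The fused positive-class probability of patient j is the convex combination
p_j = sum_i alpha_i p_ij, thresholded at 0.5.

Orientation: the default ``benefit`` mode uses the metrics as-is (larger is
better, all six are benefit criteria).  A ``cost_transform`` mode applying
x' = max(x) - x per column is retained for audit; it inverts the model
ordering and is not the default because closeness should reward the
better-performing models.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

#: canonical model order used by every weight / probability vector
MODEL_ORDER = ("DT", "RF", "XGB", "LGBM", "SVM", "NB", "GBDT")
#: canonical metric order
METRIC_NAMES = ("auc", "f1", "acc", "pre", "sen", "spe")

ORIENTATIONS = ("benefit", "cost_transform")


@dataclass
class MetricMatrix:
    """7 models x 6 metrics, rows in canonical model order."""

    values: np.ndarray
    model_names: tuple[str, ...] = MODEL_ORDER

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.model_names), len(METRIC_NAMES)):
            raise ValueError(
                f"expected {len(self.model_names)}x{len(METRIC_NAMES)} matrix, "
                f"got {self.values.shape}"
            )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MetricMatrix":
        """Build from a DataFrame indexed by model name with metric columns."""
        frame = frame.rename(columns=str.lower)
        missing = set(METRIC_NAMES) - set(frame.columns)
        if missing:
            raise ValueError(f"metric columns missing: {sorted(missing)}")
        return cls(frame.loc[list(MODEL_ORDER), list(METRIC_NAMES)].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.model_names), columns=list(METRIC_NAMES))


@dataclass
class TopsisWorkspace:
    """Intermediates of the weight computation, kept for audit."""

    transformed: np.ndarray
    normalized: np.ndarray
    weighted: np.ndarray
    pis: np.ndarray
    nis: np.ndarray
    dist_pis: np.ndarray
    dist_nis: np.ndarray
    closeness: np.ndarray


@dataclass
class FusionWeights:
    """The seven alpha_i, nonnegative and summing to one."""

    alpha: np.ndarray
    source: MetricMatrix
    orientation: str
    workspace: TopsisWorkspace

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if (self.alpha < 0).any():
            raise ValueError("fusion weights must be nonnegative")
        if abs(self.alpha.sum() - 1.0) > 1e-12:
            raise ValueError("fusion weights must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.source.model_names, map(float, self.alpha)))


def orient_metrics(matrix: np.ndarray, orientation: str = "benefit") -> np.ndarray:
    """Orient criteria so the procedure is well defined.

    ``benefit`` is the identity (all six metrics are larger-is-better);
    ``cost_transform`` applies x' = max_i(x_i) - x per column, reversing the
    per-column model ordering.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    matrix = np.asarray(matrix, dtype=float)
    if orientation == "benefit":
        return matrix.copy()
    return matrix.max(axis=0, keepdims=True) - matrix


def normalize_columns(matrix: np.ndarray) -> np.ndarray:
    """Divide each column by its Euclidean norm; all-zero columns stay zero."""
    matrix = np.asarray(matrix, dtype=float)
    norms = np.linalg.norm(matrix, axis=0, keepdims=True)
    safe = np.where(norms == 0, 1.0, norms)
    return matrix / safe


def compute_weights(
    metrics: MetricMatrix | np.ndarray | pd.DataFrame,
    index_weights: Sequence[float] | None = None,
    orientation: str = "benefit",
) -> FusionWeights:
    """Derive the seven fusion weights from a 7x6 metric matrix by TOPSIS.

    Steps: orient -> column-wise vector normalisation -> multiply columns by
    the index weights (default uniform 1/6) -> PIS/NIS as coordinate-wise
    max/min over the rows -> Euclidean distances to each -> closeness
    d-/(d-+d+) -> normalise closeness to sum 1.  If every row is identical
    (PIS = NIS) each closeness is defined as 0.5, giving uniform weights.
    """
    if isinstance(metrics, pd.DataFrame):
        metrics = MetricMatrix.from_frame(metrics)
    elif not isinstance(metrics, MetricMatrix):
        metrics = MetricMatrix(np.asarray(metrics, dtype=float))
    M = metrics.values
    if np.isnan(M).any():
        raise ValueError("metric matrix contains NaN")
    w = (
        np.full(M.shape[1], 1.0 / M.shape[1])
        if index_weights is None
        else np.asarray(index_weights, dtype=float)
    )
    if w.shape != (M.shape[1],) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("index weights must match the metric count and sum to 1")
    transformed = orient_metrics(M, orientation)
    normalized = normalize_columns(transformed)
    weighted = normalized * w
    pis = weighted.max(axis=0)
    nis = weighted.min(axis=0)
    dist_pis = np.sqrt(((weighted - pis) ** 2).sum(axis=1))
    dist_nis = np.sqrt(((weighted - nis) ** 2).sum(axis=1))
    denom = dist_pis + dist_nis
    closeness = np.where(denom == 0, 0.5, dist_nis / np.where(denom == 0, 1.0, denom))
    alpha = closeness / closeness.sum()
    ws = TopsisWorkspace(transformed, normalized, weighted, pis, nis, dist_pis, dist_nis, closeness)
    return FusionWeights(alpha, metrics, orientation, ws)


# ---------------------------------------------------------------------------
# prediction fusion


@dataclass
class PredictionSet:
    """Per-patient probability matrix p_ij (7 models x N patients)."""

    proba: np.ndarray
    model_names: tuple[str, ...] = MODEL_ORDER
    fused: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.proba = np.asarray(self.proba, dtype=float)
        if self.proba.ndim != 2 or self.proba.shape[0] != len(self.model_names):
            raise ValueError(
                f"probability matrix must be {len(self.model_names)}xN, got {self.proba.shape}"
            )
        if ((self.proba < 0) | (self.proba > 1)).any():
            raise ValueError("probabilities must lie in [0,1]")

    @property
    def n_patients(self) -> int:
        return self.proba.shape[1]


def fuse_probabilities(preds: PredictionSet, weights: FusionWeights) -> PredictionSet:
    """Fused probability p_j = sum_i alpha_i p_ij for every patient."""
    if len(weights.alpha) != preds.proba.shape[0]:
        raise ValueError("weight/model dimension mismatch")
    fused = weights.alpha @ preds.proba
    return PredictionSet(preds.proba, preds.model_names, fused)


def classify(fused: PredictionSet | np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary labels: 1 iff fused probability >= threshold."""
    p = fused.fused if isinstance(fused, PredictionSet) else np.asarray(fused, dtype=float)
    if p is None:
        raise ValueError("no fused probabilities present")
    return (p >= threshold).astype(int)


# ---------------------------------------------------------------------------
# reference worked example


def reference_metric_matrix() -> MetricMatrix:
    """The reference seven-model internal-validation metric matrix.

    Six metrics for the seven base classifiers evaluated on an internal
    validation cohort of septic-shock ICU stays; shipped as the package's
    worked example for the fusion-weight computation.
    """
    with resources.files("tcf.data").joinpath("reference_metrics.csv").open() as fh:
        frame = pd.read_csv(fh, index_col="model")
    return MetricMatrix.from_frame(frame)
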