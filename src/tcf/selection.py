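"""Entropy-ranked stepwise feature selection.

Features are ranked by Shannon entropy (continuous features discretised into
equal-frequency bins, Boolean features using their two categories directly)
and included one at a time in rank order; at each subset size a reference
classifier is fitted on the training split and scored by AUC on the
validation split.  The chosen subset is the first size maximising AUC.

The ranking direction is exposed because "informative" is genuinely
ambiguous for entropy: the default ``low_entropy_first`` treats lower
entropy as higher feature value; ``high_entropy_first`` is available for
audit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import entropy as shannon_entropy
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score

from tcf.cohort import CohortTable

DIRECTIONS = ("low_entropy_first", "high_entropy_first")


@dataclass
class FeatureRanking:
    """Ordered (feature, entropy-in-bits) pairs plus the ordering convention."""

    entries: list[tuple[str, float]]
    direction: str

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.entries]


@dataclass
class StepwiseTrace:
    """AUC as a function of subset size k, and the chosen subset."""

    ks: list[int]
    aucs: list[float]  # NaN where the fit failed
    chosen_k: int
    chosen_features: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.ks, "auc": self.aucs})


def feature_entropy(
    values: pd.Series | np.ndarray, n_bins: int = 10, boolean: bool = False
) -> float:
    """Shannon entropy of one feature in bits.

    Continuous features are discretised into ``n_bins`` equal-frequency bins
    (duplicate bin edges merged); Boolean features use their categories.
    Missing values are ignored; an all-missing column is an error.
    """
    x = pd.Series(np.asarray(values, dtype=float)).dropna()
    if x.empty:
        raise ValueError("cannot compute entropy of an all-missing column")
    if boolean or x.nunique() <= 2:
        counts = x.value_counts().to_numpy()
    else:
        binned = pd.qcut(x, q=min(n_bins, x.nunique()), duplicates="drop")
        counts = binned.value_counts().to_numpy()
    counts = counts[counts > 0]
    return float(shannon_entropy(counts, base=2))


def rank_features(
    table: CohortTable, direction: str = "low_entropy_first", n_bins: int = 10
) -> FeatureRanking:
    """Rank all features by entropy; ties broken alphabetically by name."""
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    ents = {
        s.name: feature_entropy(table.frame[s.name], n_bins, boolean=s.kind == "boolean")
        for s in table.feature_specs
    }
    reverse = direction == "high_entropy_first"
    ordered = sorted(ents.items(), key=lambda kv: (-kv[1] if reverse else kv[1], kv[0]))
    return FeatureRanking(ordered, direction)


def stepwise_select(
    train: CohortTable,
    validation: CohortTable,
    ranking: FeatureRanking,
    model_factory: Callable[[], object] | None = None,
    seed: int = 0,
) -> StepwiseTrace:
    """Forward inclusion in rank order, choosing the first AUC maximiser.

    For k = 1..K the reference model is fitted on the top-k ranked features
    of ``train`` and scored by AUC on ``validation``.  A failed fit is
    recorded as a missing point and skipped by the maximiser.
    """
    candidates = ranking.names
    unknown = set(candidates) - set(train.feature_names)
    if unknown:
        raise KeyError(f"ranking names not in training table: {sorted(unknown)}")
    model_factory = model_factory or (lambda: GradientBoostingClassifier(random_state=seed))
    ks, aucs = [], []
    y_tr, y_va = train.y, validation.y
    for k in range(1, len(candidates) + 1):
        feats = candidates[:k]
        ks.append(k)
        try:
            model = model_factory()
            model.fit(train.frame[feats], y_tr)
            proba = model.predict_proba(validation.frame[feats])[:, 1]
            aucs.append(float(roc_auc_score(y_va, proba)))
        except Exception:
            aucs.append(float("nan"))
    arr = np.asarray(aucs)
    if np.isnan(arr).all():
        raise RuntimeError("model fit failed at every subset size")
    chosen_k = ks[int(np.nanargmax(arr))]  # first maximiser on ties
    return StepwiseTrace(ks, aucs, chosen_k, candidates[:chosen_k])
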