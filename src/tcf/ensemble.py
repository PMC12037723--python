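"""The seven base classifiers and their cross-validated random search.

Canonical model order (shared with :mod:`tcf.fusion`): DT, RF, XGB, LGBM,
SVM, NB, GBDT.  Each family is tuned by seeded random search over a modest
hyperparameter space with five-fold stratified cross-validation scored by
AUC, then refitted on the full training split.  All families expose
positive-class probabilities; the SVM obtains them through Platt-style
score-to-probability calibration (during the search it is scored through
its decision function, which is rank-equivalent for AUC and far cheaper).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import loguniform, randint, uniform
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from tcf.cohort import CohortTable
from tcf.fusion import MODEL_ORDER, PredictionSet

FAMILIES = MODEL_ORDER


@dataclass
class ModelSpec:
    """One base-learner family plus its search space."""

    family: str
    search_space: dict = field(default_factory=dict)
    n_search_iterations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")


def _base_estimator(family: str, seed: int):
    if family == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if family == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if family == "XGB":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed, n_jobs=1, tree_method="hist", eval_metric="logloss",
            verbosity=0,
        )
    if family == "LGBM":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1)
    if family == "SVM":
        return SVC(random_state=seed)  # probability enabled only at refit
    if family == "NB":
        return GaussianNB()
    if family == "GBDT":
        return GradientBoostingClassifier(random_state=seed)
    raise ValueError(family)


def default_search_space(family: str) -> dict:
    """A modest, field-typical random-search space per family."""
    if family == "DT":
        return {
            "max_depth": [3, 4, 5, 6, 8, 10, None],
            "min_samples_leaf": randint(1, 25),
            "criterion": ["gini", "entropy"],
        }
    if family == "RF":
        return {
            "n_estimators": [100, 200, 300],
            "max_depth": [None, 6, 10, 16],
            "max_features": ["sqrt", "log2", 0.5],
            "min_samples_leaf": randint(1, 10),
        }
    if family == "XGB":
        return {
            "n_estimators": [100, 200, 300],
            "max_depth": randint(2, 7),
            "learning_rate": loguniform(0.01, 0.3),
            "subsample": uniform(0.6, 0.4),
            "colsample_bytree": uniform(0.6, 0.4),
        }
    if family == "LGBM":
        return {
            "n_estimators": [100, 200, 300],
            "num_leaves": [15, 31, 63],
            "learning_rate": loguniform(0.01, 0.3),
            "subsample": uniform(0.6, 0.4),
            "colsample_bytree": uniform(0.6, 0.4),
            "min_child_samples": randint(5, 40),
        }
    if family == "SVM":
        return {"C": loguniform(0.1, 100), "gamma": loguniform(1e-3, 1.0)}
    if family == "NB":
        return {"var_smoothing": loguniform(1e-11, 1e-5)}
    if family == "GBDT":
        return {
            "n_estimators": [100, 200, 300],
            "learning_rate": loguniform(0.02, 0.3),
            "max_depth": [2, 3, 4],
            "subsample": uniform(0.6, 0.4),
        }
    raise ValueError(family)


def default_model_specs(seed: int = 0, n_iter: int = 50) -> list[ModelSpec]:
    """Specs for all seven families in canonical order, sharing one seed."""
    return [ModelSpec(f, default_search_space(f), n_iter, seed) for f in FAMILIES]


def split_cohort(
    table: CohortTable, train_fraction: float = 0.8, stratified: bool = True, seed: int = 0
) -> tuple[CohortTable, CohortTable]:
    """Disjoint, exhaustive train/validation split (stratified by default)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0,1)")
    idx = np.arange(table.n_patients)
    tr, va = train_test_split(
        idx,
        train_size=train_fraction,
        stratify=table.y if stratified else None,
        random_state=seed,
    )
    return table.subset_rows(np.sort(tr)), table.subset_rows(np.sort(va))


def tune_and_fit(train: CohortTable, spec: ModelSpec, n_folds: int = 5):
    """Random search with stratified CV by AUC, refit on the full split.

    Returns the fitted estimator with ``best_params_``-style metadata in
    ``.tcf_best_params_``.
    """
    if not spec.search_space:
        raise ValueError("search space is empty")
    X, y = train.X, train.y
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=spec.seed)
    search = RandomizedSearchCV(
        _base_estimator(spec.family, spec.seed),
        spec.search_space,
        n_iter=spec.n_search_iterations,
        scoring="roc_auc",
        cv=cv,
        random_state=spec.seed,
        refit=spec.family != "SVM",
        n_jobs=1,
        error_score="raise",
    )
    search.fit(X, y)
    if spec.family == "SVM":
        # refit the winning configuration with Platt-style probability calibration
        from sklearn.calibration import CalibratedClassifierCV

        model = CalibratedClassifierCV(
            SVC(random_state=spec.seed, **search.best_params_),
            method="sigmoid",
            cv=n_folds,
            ensemble=False,
        )
        model.fit(X, y)
    else:
        model = search.best_estimator_
    model.tcf_best_params_ = dict(search.best_params_)
    model.tcf_cv_auc_ = float(search.best_score_)
    return model


def fit_ensemble(
    train: CohortTable, specs: Sequence[ModelSpec] | None = None, n_folds: int = 5
) -> dict[str, object]:
    """Tune and fit all seven families; returns {family: fitted model}."""
    specs = list(specs) if specs is not None else default_model_specs()
    families = tuple(s.family for s in specs)
    if families != FAMILIES:
        raise ValueError(f"specs must cover the canonical families {FAMILIES} in order")
    return {s.family: tune_and_fit(train, s, n_folds) for s in specs}


def predict_matrix(models: Mapping[str, object], table: CohortTable) -> PredictionSet:
    """Positive-class probability matrix p_ij in canonical model order."""
    missing = set(MODEL_ORDER) - set(models)
    if missing:
        raise ValueError(f"models missing for families: {sorted(missing)}")
    rows = []
    for family in MODEL_ORDER:
        model = models[family]
        if not hasattr(model, "predict_proba"):
            raise ValueError(f"{family} model lacks probability output")
        rows.append(model.predict_proba(table.X)[:, 1])
    return PredictionSet(np.vstack(rows))
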