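"""Feature-processing cascade applied before modeling.

Stages run in a fixed order, each consuming the survivors of the previous
one and logging every keep/drop decision with its triggering statistic:

1. missing-rate filter — drop features missing in strictly more than 30 %
   of patients (too sparse to be worth imputing);
2. Boolean-variance filter — drop Boolean features whose majority category
   exceeds 90 % agreement (Bernoulli variance p(1-p) below the 0.9x0.1
   bound carries almost no information);
3. correlation filter — for feature pairs with |Pearson r| >= 0.7 keep the
   member with the larger univariate AUC against the outcome;
4. imputation tournament — four candidate imputers compete on held-out AUC
   of a fixed reference classifier; the winner imputes everything downstream;
5. (entropy-ranked stepwise selection lives in :mod:`tcf.selection`);
6. min-max scaling fitted on training data, and 1:1 SMOTE oversampling of
   the minority class.

Boundary semantics are deliberate: "greater than 30 %" and "more than 90 %
agreement" are strict inequalities, "correlation not less than 0.7" is
inclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from tcf.cohort import CohortTable, SchemaError

# ---------------------------------------------------------------------------
# audit trail


@dataclass
class StageRecord:
    feature: str
    statistic: float | None
    action: str  # "kept" | "dropped"
    reason: str


@dataclass
class Stage:
    name: str
    records: list[StageRecord] = field(default_factory=list)

    @property
    def kept(self) -> list[str]:
        return [r.feature for r in self.records if r.action == "kept"]

    @property
    def dropped(self) -> list[str]:
        return [r.feature for r in self.records if r.action == "dropped"]


@dataclass
class PreprocessReport:
    """Audit trail of the cascade: every decision, plus the imputer tournament."""

    stages: list[Stage] = field(default_factory=list)
    imputer_choice: str | None = None
    tournament_aucs: dict[str, float] = field(default_factory=dict)

    def add(self, stage: Stage) -> None:
        self.stages.append(stage)

    def counts(self) -> list[tuple[str, int]]:
        """(stage name, number of surviving features) after each stage."""
        return [(s.name, len(s.kept)) for s in self.stages]

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "records": [
                        {
                            "feature": r.feature,
                            "statistic": r.statistic,
                            "action": r.action,
                            "reason": r.reason,
                        }
                        for r in s.records
                    ],
                }
                for s in self.stages
            ],
            "imputer_choice": self.imputer_choice,
            "tournament_aucs": self.tournament_aucs,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# filters


def filter_missing_rate(
    table: CohortTable, threshold: float = 0.30
) -> tuple[CohortTable, Stage]:
    """Drop features whose missing fraction strictly exceeds ``threshold``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0,1)")
    stage = Stage("missing_rate")
    drop = []
    for name in table.feature_names:
        frac = float(table.frame[name].isna().mean())
        if frac > threshold:
            drop.append(name)
            stage.records.append(
                StageRecord(name, frac, "dropped", f"missing rate {frac:.3f} > {threshold}")
            )
        else:
            stage.records.append(StageRecord(name, frac, "kept", "missing rate ok"))
    return table.drop_features(drop), stage


def filter_boolean_variance(
    table: CohortTable, agreement: float = 0.90
) -> tuple[CohortTable, Stage]:
    """Drop Boolean features with more than ``agreement`` majority agreement.

    With p the proportion of ones among non-missing entries, a feature is
    dropped iff max(p, 1-p) > agreement — equivalently its Bernoulli variance
    p(1-p) falls below agreement*(1-agreement).  The variance is what the
    report records.
    """
    stage = Stage("boolean_variance")
    drop = []
    for spec in table.feature_specs:
        name = spec.name
        if spec.kind != "boolean":
            stage.records.append(StageRecord(name, None, "kept", "not boolean"))
            continue
        col = table.frame[name].dropna()
        if col.empty:
            drop.append(name)
            stage.records.append(StageRecord(name, None, "dropped", "empty"))
            continue
        p = float(col.mean())
        var = p * (1 - p)
        if max(p, 1 - p) > agreement:
            drop.append(name)
            stage.records.append(
                StageRecord(name, var, "dropped", f"agreement {max(p, 1 - p):.3f} > {agreement}")
            )
        else:
            stage.records.append(StageRecord(name, var, "kept", "variance ok"))
    return table.drop_features(drop), stage


def univariate_auc(x: pd.Series | np.ndarray, y: pd.Series | np.ndarray) -> float:
    """Direction-free AUC of a raw feature as a score: max(A, 1-A).

    Computed on complete observations only; NaN if fewer than 2 per class.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x)
    x, y = x[ok], y[ok]
    if len(np.unique(y)) < 2:
        return float("nan")
    a = roc_auc_score(y, x)
    return float(max(a, 1 - a))


def filter_correlation(
    table: CohortTable,
    r_threshold: float = 0.7,
    auc_fn: Callable[[pd.Series, pd.Series], float] | None = None,
    min_pairs: int = 3,
) -> tuple[CohortTable, Stage]:
    """Resolve highly correlated feature pairs, keeping the better predictor.

    Pairwise-complete Pearson correlations are computed between all feature
    pairs; pairs with |r| >= ``r_threshold`` are processed in descending |r|
    (ties broken by name pair).  In each pair the member with the lower
    univariate AUC against the outcome is dropped; pairs whose member was
    already dropped are skipped, as are pairs with fewer than ``min_pairs``
    complete observations (logged).
    """
    auc_fn = auc_fn or univariate_auc
    stage = Stage("correlation")
    X = table.X
    y = table.y
    corr = X.corr(method="pearson", min_periods=min_pairs)
    n_complete = X.notna().astype(int).T @ X.notna().astype(int)
    names = list(X.columns)
    flagged = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r = corr.loc[a, b]
            if np.isnan(r):
                if n_complete.loc[a, b] < min_pairs:
                    stage.records.append(
                        StageRecord(a, None, "kept", f"pair ({a},{b}) skipped: <{min_pairs} complete pairs")
                    )
                continue
            if abs(r) >= r_threshold:
                flagged.append((abs(r), *sorted((a, b))))
    flagged.sort(key=lambda t: (-t[0], t[1], t[2]))
    dropped: set[str] = set()
    for r_abs, a, b in flagged:
        if a in dropped or b in dropped:
            continue
        auc_a, auc_b = auc_fn(X[a], y), auc_fn(X[b], y)
        # lower-AUC member goes; tie keeps the alphabetically first
        loser = b if (np.isnan(auc_b) or auc_b <= auc_a) else a
        keeper = a if loser == b else b
        dropped.add(loser)
        stage.records.append(
            StageRecord(
                loser,
                float(r_abs),
                "dropped",
                f"|r|={r_abs:.3f} with {keeper}; univariate AUC "
                f"{auc_a:.3f}({a}) vs {auc_b:.3f}({b})",
            )
        )
    for name in names:
        if name not in dropped:
            stage.records.append(StageRecord(name, None, "kept", "no unresolved pair"))
    return table.drop_features(dropped), stage


# ---------------------------------------------------------------------------
# imputation


class ChainedImputer:
    """Chained-equations imputation with a per-column conditional model.

    Missing entries are initialised with column means (Boolean columns: the
    mode) and refined over sweeps: each incomplete column is regressed on all
    the others and its missing entries replaced by the fitted conditional
    mean.  Boolean columns use a classifier, continuous columns a regressor;
    the ``conditional`` family names the discrete-column model ("logistic"
    pairs with linear regression, "knn" with k-NN regression).  One completed
    dataset is produced (no posterior draws).
    """

    def __init__(self, conditional: str = "logistic", n_sweeps: int = 5, seed: int = 0):
        if conditional not in ("logistic", "knn"):
            raise ValueError("conditional must be 'logistic' or 'knn'")
        self.conditional = conditional
        self.n_sweeps = n_sweeps
        self.seed = seed
        self._models: dict[str, object] = {}

    def _make_models(self, boolean: bool):
        from sklearn.linear_model import LinearRegression, LogisticRegression
        from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        if self.conditional == "logistic":
            if boolean:
                return make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000))
            return LinearRegression()
        return KNeighborsClassifier(5) if boolean else KNeighborsRegressor(5)

    def fit_transform_frame(self, X: pd.DataFrame, boolean_cols: set[str]) -> pd.DataFrame:
        work = X.copy()
        na_mask = X.isna()
        # initialisation
        for c in work.columns:
            col = work[c]
            if col.isna().all():
                raise ValueError(f"column {c!r} entirely missing")
            fill = col.mode().iloc[0] if c in boolean_cols else col.mean()
            work[c] = col.fillna(fill)
        incomplete = [c for c in X.columns if na_mask[c].any()]
        for _ in range(self.n_sweeps):
            for c in incomplete:
                obs = ~na_mask[c]
                others = [o for o in work.columns if o != c]
                model = self._make_models(c in boolean_cols)
                target = X.loc[obs, c]
                if c in boolean_cols and target.nunique() < 2:
                    continue  # degenerate observed part; keep the mode fill
                model.fit(work.loc[obs, others], target)
                pred = model.predict(work.loc[na_mask[c], others])
                work.loc[na_mask[c], c] = pred
        return work


class _SklearnImputerAdapter:
    """Wrap an sklearn imputer to the frame-in/frame-out interface."""

    def __init__(self, factory):
        self.factory = factory

    def fit_transform_frame(self, X: pd.DataFrame, boolean_cols: set[str]) -> pd.DataFrame:
        imp = self.factory()
        out = pd.DataFrame(imp.fit_transform(X), columns=X.columns, index=X.index)
        if out.shape != X.shape:
            raise ValueError("imputer dropped columns")
        for c in boolean_cols:
            out[c] = out[c].round().clip(0, 1)
        return out


def default_imputers(seed: int = 0) -> list[tuple[str, object]]:
    """The four candidate imputers, in tournament tie-break order."""
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer, KNNImputer
    from sklearn.linear_model import Ridge

    return [
        ("knn", _SklearnImputerAdapter(lambda: KNNImputer(n_neighbors=5))),
        ("mice_logistic", ChainedImputer("logistic", seed=seed)),
        ("mice_knn", ChainedImputer("knn", seed=seed)),
        (
            "ridge",
            _SklearnImputerAdapter(
                lambda: IterativeImputer(
                    # stability-level penalty: near-OLS conditionals, but exact
                    # collinearity cannot blow up the linear solve
                    estimator=Ridge(alpha=1e-6), max_iter=30, tol=1e-7, random_state=seed
                )
            ),
        ),
    ]


def impute_table(table: CohortTable, imputer) -> CohortTable:
    boolean_cols = {s.name for s in table.feature_specs if s.kind == "boolean"}
    frame = table.frame.copy()
    frame[table.feature_names] = imputer.fit_transform_frame(table.X, boolean_cols)
    return table.with_frame(frame)


def imputation_tournament(
    train: CohortTable,
    methods: Sequence[tuple[str, object]] | None = None,
    reference_model: Callable[[], object] | None = None,
    seed: int = 0,
    holdout_fraction: float = 0.25,
) -> tuple[tuple[str, object], PreprocessReport]:
    """Pick the imputer whose completed data best supports a fixed classifier.

    Each candidate imputes the training table; a reference gradient-boosted
    classifier (fixed configuration and seed) is trained on an internal
    stratified split of the completed data and scored by AUC on the held-out
    part.  The highest AUC wins; ties go to list order; a candidate that
    raises is disqualified and logged.
    """
    methods = list(methods) if methods is not None else default_imputers(seed)
    reference_model = reference_model or (
        lambda: GradientBoostingClassifier(random_state=seed)
    )
    report = PreprocessReport()
    idx = np.arange(train.n_patients)
    fit_idx, held_idx = train_test_split(
        idx, test_size=holdout_fraction, stratify=train.y, random_state=seed
    )
    best: tuple[str, object] | None = None
    best_auc = -np.inf
    for name, imputer in methods:
        try:
            completed = impute_table(train, imputer)
            model = reference_model()
            model.fit(completed.X.iloc[fit_idx], completed.y.iloc[fit_idx])
            proba = model.predict_proba(completed.X.iloc[held_idx])[:, 1]
            auc = float(roc_auc_score(completed.y.iloc[held_idx], proba))
        except Exception as exc:  # disqualified, logged
            report.tournament_aucs[name] = float("nan")
            report.add(Stage(f"tournament:{name}", [StageRecord(name, None, "dropped", f"failed: {exc}")]))
            continue
        report.tournament_aucs[name] = auc
        if auc > best_auc:  # strict: ties keep the earlier method
            best, best_auc = (name, imputer), auc
    if best is None:
        raise RuntimeError("every imputation method failed")
    report.imputer_choice = best[0]
    return best, report


# ---------------------------------------------------------------------------
# scaling


@dataclass
class ScalerState:
    """Per-feature (min, max) fitted on training data."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if hi < lo:
                raise ValueError(f"max < min for feature {name!r}")


def fit_minmax(train: CohortTable) -> ScalerState:
    bounds = {}
    for name in train.feature_names:
        col = train.frame[name]
        bounds[name] = (float(col.min()), float(col.max()))
    return ScalerState(bounds)


def apply_minmax(table: CohortTable, state: ScalerState) -> CohortTable:
    """(x - min)/(max - min), clipped to [0,1]; constant features map to 0."""
    frame = table.frame.copy()
    for name in table.feature_names:
        if name not in state.bounds:
            raise SchemaError(f"scaler has no bounds for feature {name!r}")
        lo, hi = state.bounds[name]
        col = frame[name]
        if hi == lo:
            frame[name] = np.where(col.isna(), np.nan, 0.0)
        else:
            frame[name] = ((col - lo) / (hi - lo)).clip(0.0, 1.0)
    return table.with_frame(frame)


def invert_minmax(table: CohortTable, state: ScalerState) -> CohortTable:
    frame = table.frame.copy()
    for name in table.feature_names:
        lo, hi = state.bounds[name]
        frame[name] = frame[name] * (hi - lo) + lo
    return table.with_frame(frame)


# ---------------------------------------------------------------------------
# SMOTE


def smote_oversample(
    train: CohortTable, ratio: float = 1.0, k_neighbors: int = 5, seed: int = 0
) -> CohortTable:
    """Balance classes by synthetic minority oversampling.

    Synthetic minority rows are convex combinations ``x + u (x_nn - x)``,
    u ~ Uniform(0,1), of a random minority point and one of its ``k``
    minority-class nearest neighbours (Euclidean), until the minority count
    reaches ``ratio`` times the majority count.  Original rows are preserved
    unchanged.  Requires complete (post-imputation) features.
    """
    X = train.X
    if X.isna().any().any():
        raise ValueError("SMOTE requires complete data; impute first")
    y = train.y.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_needed = int(round(ratio * n_maj)) - n_min
    if n_needed <= 0:
        return train
    if n_min < 2:
        raise ValueError("minority class has no neighbours to interpolate with")
    k = min(k_neighbors, n_min - 1)
    Xm = X.to_numpy()[y == minority]
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, neigh = nn.kneighbors(Xm)  # column 0 is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(Xm), size=n_needed)
    pick = rng.integers(1, k + 1, size=n_needed)
    u = rng.uniform(0, 1, size=n_needed)
    synth = Xm[base] + u[:, None] * (Xm[neigh[base, pick]] - Xm[base])
    new = pd.DataFrame(synth, columns=X.columns)
    for spec in train.feature_specs:  # interpolated Booleans snap back to {0,1}
        if spec.kind == "boolean":
            new[spec.name] = new[spec.name].round().clip(0, 1)
    new[train.outcome_name] = minority
    for spec in train.specs:
        if spec.role == "identifier":
            new[spec.name] = np.nan
    frame = pd.concat([train.frame, new[train.frame.columns.tolist()]], ignore_index=True)
    return train.with_frame(frame)
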