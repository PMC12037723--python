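"""Filtering cascade, imputation tournament, scaling and SMOTE."""

import numpy as np
import pandas as pd
import pytest

from tcf.cohort import SchemaError
from tcf.preprocess import (
    ChainedImputer,
    apply_minmax,
    default_imputers,
    filter_boolean_variance,
    filter_correlation,
    filter_missing_rate,
    fit_minmax,
    imputation_tournament,
    impute_table,
    invert_minmax,
    smote_oversample,
    univariate_auc,
)

from conftest import make_table


def _with_missing(values, n_missing):
    v = list(map(float, values))
    for i in range(n_missing):
        v[i] = np.nan
    return v


# -- missing-rate filter -------------------------------------------------


def test_missing_rate_boundary_is_strict():
    """40% missing is dropped; exactly 30% is kept ('greater than')."""
    y = [0, 1] * 5
    t = make_table(
        {"f40": _with_missing(range(10), 4), "f30": _with_missing(range(10), 3)}, y
    )
    out, stage = filter_missing_rate(t, 0.30)
    assert out.feature_names == ["f30"]
    assert stage.dropped == ["f40"]


def test_missing_rate_counts_by_enumeration():
    """Missing fractions {0, .1, .31, .5, .29} at n=100 -> 3 survivors."""
    y = [0, 1] * 50
    fracs = {"a": 0, "b": 10, "c": 31, "d": 50, "e": 29}
    t = make_table({k: _with_missing(range(100), m) for k, m in fracs.items()}, y)
    out, _ = filter_missing_rate(t, 0.30)
    assert sorted(out.feature_names) == ["a", "b", "e"]


# -- Boolean-variance filter ---------------------------------------------


@pytest.mark.parametrize(
    "p, kept",
    [(0.95, False), (0.5, True), (0.90, True)],  # 'more than 90%' is strict
)
def test_boolean_agreement_boundaries(p, kept):
    n = 100
    vals = [1.0] * int(p * n) + [0.0] * (n - int(p * n))
    t = make_table({"b": vals}, [0, 1] * 50, kinds={"b": "boolean"})
    out, stage = filter_boolean_variance(t, 0.90)
    assert ("b" in out.feature_names) is kept
    rec = next(r for r in stage.records if r.feature == "b")
    assert rec.statistic == pytest.approx(p * (1 - p))  # Bernoulli variance logged


def test_boolean_filter_ignores_continuous_and_uses_nonmissing_proportion():
    t = make_table(
        {"cont": [0.0] * 99 + [1.0], "b": [1.0] * 9 + [np.nan] * 91},
        [0, 1] * 50,
        kinds={"b": "boolean"},
    )
    out, _ = filter_boolean_variance(t, 0.90)
    assert "cont" in out.feature_names  # continuous never dropped here
    assert "b" not in out.feature_names  # p=1 among non-missing


def test_all_missing_boolean_dropped_as_empty():
    t = make_table({"b": [np.nan] * 4, "c": [1, 2, 3, 4]}, [0, 1, 0, 1], kinds={"b": "boolean"})
    out, stage = filter_boolean_variance(t)
    rec = next(r for r in stage.records if r.feature == "b")
    assert rec.reason == "empty" and "b" not in out.feature_names


# -- correlation filter ---------------------------------------------------


def test_duplicate_feature_resolved_by_univariate_auc(rng):
    n = 200
    x = rng.standard_normal(n)
    y = (x + rng.standard_normal(n) > 0).astype(float)
    t = make_table({"orig": x, "copy": x}, y)
    out, stage = filter_correlation(t, 0.7)
    assert len(out.feature_names) == 1
    # identical AUCs: alphabetically first member kept
    assert out.feature_names == ["copy"]


def test_independent_features_both_kept(rng):
    n = 500
    t = make_table({"a": rng.standard_normal(n), "b": rng.standard_normal(n)},
                   rng.binomial(1, 0.5, n))
    out, _ = filter_correlation(t, 0.7)
    assert sorted(out.feature_names) == ["a", "b"]


def test_chained_pairs_resolved_in_descending_r_order(rng):
    """f1~f2 (r~.9), f2~f3 (r~.8), AUCs (.70,.60,.65): f2 dropped, pair f2-f3 moot."""
    n = 4000
    rng = np.random.default_rng(7)
    z = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    f2 = 0.9 * z + np.sqrt(0.19) * e2
    # corr(f3,f2)=.80, corr(f3,f1)=.50 so only the stated two pairs are flagged
    f3 = 0.5 * z + 0.803 * e2 + np.sqrt(0.105) * rng.standard_normal(n)
    y = rng.binomial(1, 0.5, n).astype(float)

    target = {"f1": 0.70, "f2": 0.60, "f3": 0.65}

    def fake_auc(x, yy):
        for name, col in t.X.items():
            if np.array_equal(col.to_numpy(), np.asarray(x)):
                return target[name]
        raise AssertionError("unknown column")

    t = make_table({"f1": z, "f2": f2, "f3": f3}, y)
    corr = t.X.corr()
    assert abs(corr.loc["f1", "f2"]) >= 0.7 and abs(corr.loc["f2", "f3"]) >= 0.7
    assert abs(corr.loc["f1", "f3"]) < 0.7
    assert abs(corr.loc["f1", "f2"]) > abs(corr.loc["f2", "f3"])
    out, stage = filter_correlation(t, 0.7, auc_fn=fake_auc)
    assert sorted(out.feature_names) == ["f1", "f3"]
    assert stage.dropped == ["f2"]


def test_short_pairs_skipped():
    """A correlation with <3 complete pairs is skipped, not resolved."""
    t = make_table(
        {"a": [1, 2, np.nan, np.nan, 5], "b": [1, 2, 3, 4, np.nan]},
        [0, 1, 0, 1, 0],
    )
    out, _ = filter_correlation(t, 0.7, min_pairs=3)
    assert sorted(out.feature_names) == ["a", "b"]


def test_univariate_auc_is_direction_free(rng):
    n = 300
    x = rng.standard_normal(n)
    y = (x > 0.5).astype(float)
    assert univariate_auc(x, y) == univariate_auc(-x, y)
    assert univariate_auc(x, y) > 0.9


# -- imputation tournament -------------------------------------------------


def _holed_cohort(rng, n=300):
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    y = (x1 + 0.3 * rng.standard_normal(n) > 0.5).astype(float)
    x1 = np.where(rng.uniform(size=n) < 0.15, np.nan, x1)
    return make_table({"x1": x1, "x2": x2}, y)


def test_no_missing_ties_break_by_method_order(rng):
    n = 200
    x = rng.standard_normal(n)
    y = (x > 0).astype(float)
    t = make_table({"x": x, "z": rng.standard_normal(n)}, y)
    (name, _), report = imputation_tournament(t, seed=0)
    aucs = list(report.tournament_aucs.values())
    assert all(a == pytest.approx(aucs[0]) for a in aucs)  # identical completed tables
    assert name == "knn"  # first method in list order wins the tie


def test_ridge_imputer_recovers_exact_linear_structure(rng):
    n = 500
    x = rng.standard_normal(n)
    yv = 2 * x + 1
    mask = rng.uniform(size=n) < 0.2
    truth = yv[mask].copy()
    y_holed = yv.copy()
    y_holed[mask] = np.nan
    t = make_table({"x": x, "lin": y_holed}, rng.binomial(1, 0.5, n))
    ridge = dict(default_imputers(seed=0))["ridge"]
    completed = impute_table(t, ridge)
    rmse = np.sqrt(np.mean((completed.frame.loc[mask, "lin"].to_numpy() - truth) ** 2))
    assert rmse < 1e-6


def test_failed_method_disqualified(rng):
    class Exploding:
        def fit_transform_frame(self, X, boolean_cols):
            raise RuntimeError("boom")

    t = _holed_cohort(rng)
    methods = [("boom", Exploding())] + default_imputers(seed=0)[:1]
    (name, _), report = imputation_tournament(t, methods=methods, seed=0)
    assert name == "knn"
    assert np.isnan(report.tournament_aucs["boom"])


def test_chained_imputer_fills_booleans_with_categories(rng):
    n = 200
    x = rng.standard_normal(n)
    b = (x > 0).astype(float)
    b[rng.uniform(size=n) < 0.2] = np.nan
    t = make_table({"x": x, "b": b}, rng.binomial(1, 0.5, n), kinds={"b": "boolean"})
    completed = impute_table(t, ChainedImputer("logistic"))
    assert completed.frame["b"].isin([0.0, 1.0]).all()


# -- min-max scaling -------------------------------------------------------


def test_minmax_formula_and_degenerate_and_clipping():
    train = make_table({"f": [2, 4, 6], "const": [5, 5, 5]}, [0, 1, 0])
    state = fit_minmax(train)
    out = apply_minmax(train, state)
    assert out.frame["f"].tolist() == [0.0, 0.5, 1.0]
    assert out.frame["const"].tolist() == [0.0, 0.0, 0.0]
    external = make_table({"f": [10, -1], "const": [5, 5]}, [0, 1])
    ext = apply_minmax(external, state)
    assert ext.frame["f"].tolist() == [1.0, 0.0]  # clipped into [0,1]


def test_minmax_inverse_identity_in_range(rng):
    train = make_table({"f": rng.uniform(-3, 9, 50)}, rng.binomial(1, 0.5, 50))
    state = fit_minmax(train)
    back = invert_minmax(apply_minmax(train, state), state)
    np.testing.assert_allclose(back.frame["f"], train.frame["f"], rtol=1e-12)


def test_minmax_unknown_column_is_schema_error():
    train = make_table({"f": [1, 2]}, [0, 1])
    state = fit_minmax(train)
    other = make_table({"g": [1, 2]}, [0, 1])
    with pytest.raises(SchemaError):
        apply_minmax(other, state)


# -- SMOTE -----------------------------------------------------------------


def test_smote_counts_100_20_to_100_100(rng):
    n_neg, n_pos = 100, 20
    X = rng.standard_normal((n_neg + n_pos, 3))
    y = np.r_[np.zeros(n_neg), np.ones(n_pos)]
    t = make_table({f"f{i}": X[:, i] for i in range(3)}, y)
    out = smote_oversample(t, 1.0, k_neighbors=5, seed=0)
    counts = out.y.value_counts()
    assert counts[0] == 100 and counts[1] == 100
    # original rows preserved verbatim
    pd.testing.assert_frame_equal(out.frame.iloc[: len(t.frame)], t.frame)


def test_smote_synthetic_points_on_segment():
    a, b = -2.0, 4.0
    t = make_table({"x": [a, b] + [0.1 * i for i in range(20)]},
                   [1, 1] + [0] * 20)
    out = smote_oversample(t, 1.0, k_neighbors=1, seed=3)
    synth = out.frame["x"].iloc[22:]
    assert len(synth) == 18
    assert ((synth >= a) & (synth <= b)).all()


def test_smote_balanced_table_unchanged(rng):
    t = make_table({"x": rng.standard_normal(10)}, [0, 1] * 5)
    out = smote_oversample(t, seed=0)
    pd.testing.assert_frame_equal(out.frame, t.frame)


def test_smote_singleton_minority_errors(rng):
    t = make_table({"x": rng.standard_normal(6)}, [0] * 5 + [1])
    with pytest.raises(ValueError):
        smote_oversample(t, seed=0)


def test_smote_requires_complete_data():
    t = make_table({"x": [1.0, np.nan, 3.0, 4.0]}, [0, 0, 1, 1])
    with pytest.raises(ValueError):
        smote_oversample(t, seed=0)
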