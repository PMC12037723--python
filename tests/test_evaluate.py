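"""Six-metric scoring, bootstrap CIs, calibration, DCA, importance."""

import numpy as np
import pandas as pd
import pytest

from tcf.evaluate import (
    TREE_FAMILIES,
    aggregate_importance,
    bootstrap_ci,
    calibration_curve,
    confusion_counts,
    decision_curve,
    extract_importances,
    score_metrics,
)
from tcf.fusion import MetricMatrix, compute_weights


def brute_force_auc(labels, scores):
    """All-pairs Mann-Whitney with ties counted one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_perfect_separation_all_metrics_one():
    y = np.array([1, 1, 0, 0])
    p = np.array([0.9, 0.9, 0.1, 0.1])
    assert all(v == 1.0 for v in score_metrics(y, p).values())


def test_hand_derived_confusion_metrics():
    """tp=2 fn=2 tn=6 fp=0 -> SEN .5, SPE 1, ACC .8, PRE 1, F1 2/3."""
    y = np.r_[np.ones(4), np.zeros(6)]
    p = np.r_[0.9, 0.8, 0.1, 0.2, np.full(6, 0.1)]
    m = score_metrics(y, p)
    assert m["sen"] == pytest.approx(0.5)
    assert m["spe"] == pytest.approx(1.0)
    assert m["acc"] == pytest.approx(0.8)
    assert m["pre"] == pytest.approx(1.0)
    assert m["f1"] == pytest.approx(2 / 3)
    c = confusion_counts(y, p)
    assert (c.tp, c.fn, c.tn, c.fp) == (2, 2, 6, 0)


def test_constant_probabilities_auc_half():
    y = np.array([0, 1, 0, 1])
    m = score_metrics(y, np.full(4, 0.5))
    assert m["auc"] == pytest.approx(0.5)


def test_no_predicted_positives_precision_zero_with_warning():
    y = np.array([0, 1, 0, 1])
    with pytest.warns(UserWarning):
        m = score_metrics(y, np.full(4, 0.2))
    assert m["pre"] == 0.0 and m["f1"] == 0.0


def test_single_class_auc_undefined():
    with pytest.raises(ValueError):
        score_metrics(np.ones(5), np.full(5, 0.5))


def test_auc_matches_brute_force_on_random_inputs(rng):
    for _ in range(20):
        n = int(rng.integers(5, 40))
        y = rng.binomial(1, 0.5, n)
        if y.min() == y.max():
            continue
        p = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)  # ties likely
        assert score_metrics(y, p)["auc"] == pytest.approx(brute_force_auc(y, p))


# -- bootstrap -------------------------------------------------------------


def test_bootstrap_constant_metric_zero_width():
    y = np.array([1, 1, 0, 0] * 10)
    p = np.where(y == 1, 0.9, 0.1)
    ci = bootstrap_ci(y, p, "auc", n_resamples=100, seed=0)
    assert ci.lower == ci.upper == ci.point == 1.0


def test_bootstrap_deterministic_under_seed(rng):
    y = rng.binomial(1, 0.3, 100)
    p = np.clip(rng.uniform(size=100) + 0.3 * y, 0, 1)
    a = bootstrap_ci(y, p, "auc", 200, seed=11)
    b = bootstrap_ci(y, p, "auc", 200, seed=11)
    assert (a.lower, a.upper) == (b.lower, b.upper)


def test_bootstrap_width_shrinks_with_n(rng):
    widths = []
    for n in (100, 400, 1600):
        y = rng.binomial(1, 0.3, n)
        p = np.clip(0.3 + 0.3 * y + 0.2 * rng.standard_normal(n), 0, 1)
        ci = bootstrap_ci(y, p, "auc", 300, seed=0)
        widths.append(ci.upper - ci.lower)
    assert widths[0] > widths[1] > widths[2]


def test_bootstrap_metric_failure_rate_errors():
    y = np.array([0, 0, 0, 1])  # resamples almost always lack the positive

    def fragile(yy, pp):
        if yy.sum() == 0 or yy.sum() == len(yy):
            raise ValueError("one class")
        raise RuntimeError("always fails otherwise too")

    with pytest.raises(RuntimeError):
        bootstrap_ci(y, np.full(4, 0.5), fragile, 50, seed=0, max_redraws=2)


# -- calibration -----------------------------------------------------------


def test_calibrated_data_reliability(rng):
    n = 10000
    p = rng.uniform(size=n)
    y = rng.binomial(1, p)
    curve = calibration_curve(y, p, n_bins=10)
    assert (curve["observed_rate"] - curve["mean_predicted"]).abs().max() < 0.05


def test_single_bin_point_mass():
    y = np.r_[np.ones(3), np.zeros(7)]
    curve = calibration_curve(y, np.full(10, 0.3), n_bins=10)
    assert len(curve) == 1
    assert curve.loc[0, "mean_predicted"] == pytest.approx(0.3)
    assert curve.loc[0, "observed_rate"] == pytest.approx(0.3)


def test_empty_bins_omitted():
    y = np.array([0, 1, 0, 1])
    curve = calibration_curve(y, np.array([0.05, 0.05, 0.95, 0.95]), n_bins=10)
    assert len(curve) == 2
    assert curve["n"].sum() == 4


# -- decision curves -------------------------------------------------------


def test_treat_none_identically_zero(rng):
    y = rng.binomial(1, 0.3, 200)
    p = rng.uniform(size=200)
    dca = decision_curve(y, p, np.linspace(0.05, 0.95, 19))
    assert (dca["nb_none"] == 0).all()


def test_treat_all_tends_to_prevalence_at_small_threshold(rng):
    y = rng.binomial(1, 0.3, 500)
    dca = decision_curve(y, rng.uniform(size=500), [1e-6])
    assert dca.loc[0, "nb_all"] == pytest.approx(y.mean(), abs=1e-4)


def test_perfect_model_net_benefit_is_prevalence(rng):
    y = rng.binomial(1, 0.25, 400).astype(float)
    dca = decision_curve(y, y, np.linspace(0.1, 0.9, 9))
    np.testing.assert_allclose(dca["nb_model"], y.mean(), atol=1e-12)
    assert (dca["nb_model"] >= dca["nb_all"] - 1e-12).all()
    assert (dca["nb_model"] >= 0).all()


def test_all_positive_predictions_coincide_with_treat_all(rng):
    y = rng.binomial(1, 0.3, 300)
    dca = decision_curve(y, np.ones(300), np.linspace(0.1, 0.9, 9))
    np.testing.assert_allclose(dca["nb_model"], dca["nb_all"], atol=1e-12)
    dca0 = decision_curve(y, np.zeros(300), np.linspace(0.1, 0.9, 9))
    np.testing.assert_allclose(dca0["nb_model"], 0.0, atol=1e-12)


def test_thresholds_outside_unit_interval_rejected(rng):
    with pytest.raises(ValueError):
        decision_curve(np.array([0, 1]), np.array([0.2, 0.8]), [0.0, 0.5])


# -- importance aggregation -------------------------------------------------


def _uniform_weights():
    return compute_weights(MetricMatrix(np.tile([0.7, 0.5, 0.6, 0.4, 0.5, 0.8], (7, 1))))


def test_agreeing_models_aggregate_to_same_vector():
    v = pd.Series([0.5, 0.3, 0.2], index=["a", "b", "c"])
    imps = pd.DataFrame({f: v for f in TREE_FAMILIES})
    out = aggregate_importance(imps, _uniform_weights())
    np.testing.assert_allclose(out["aggregated"].sort_index(), v.sort_index())


def test_disjoint_importances_with_equal_weights_average():
    imps = pd.DataFrame(
        {f: ([1.0, 0.0] if i % 2 == 0 else [0.0, 1.0]) for i, f in enumerate(TREE_FAMILIES)},
        index=["a", "b"],
    )
    out = aggregate_importance(imps, _uniform_weights())
    # three models vote (1,0), two vote (0,1), all with equal alpha
    np.testing.assert_allclose(out["aggregated"].sort_index(), [0.6, 0.4])


def test_aggregate_sums_to_one(rng):
    imps = pd.DataFrame(
        {f: rng.dirichlet(np.ones(6)) for f in TREE_FAMILIES},
        index=list("abcdef"),
    )
    w = compute_weights(MetricMatrix(rng.uniform(0.3, 0.9, (7, 6))))
    out = aggregate_importance(imps, w)
    assert out["aggregated"].sum() == pytest.approx(1.0)


def test_wrong_importance_columns_rejected():
    imps = pd.DataFrame({"DT": [1.0]}, index=["a"])
    with pytest.raises(ValueError):
        aggregate_importance(imps, _uniform_weights())


def test_extract_importances_normalised(small_cohort):
    from sklearn.tree import DecisionTreeClassifier

    m = DecisionTreeClassifier(random_state=0).fit(small_cohort.X, small_cohort.y)
    models = {f: m for f in TREE_FAMILIES}
    imps = extract_importances(models, small_cohort.feature_names)
    np.testing.assert_allclose(imps.sum(axis=0), 1.0)
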