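"""Backward-elimination protocol: schedule, nesting, leakage, determinism."""

import numpy as np
import pandas as pd
import pytest

from brainmeth import (
    MethylationMatrix,
    SelectionConfig,
    aggregate_importance,
    backward_elimination_cv,
    halving_schedule,
    performance_summary,
    permutation_null,
)
from brainmeth.rf_selection import ModelRecord

from conftest import two_class_matrix

SMALL = SelectionConfig(n_start=300, n_steps=8, n_trees=100, n_repeats=2, seed=11)


@pytest.fixture(scope="module")
def separable():
    """60-sample, 400-probe, 2-class matrix with 20 strong planted probes."""
    return two_class_matrix(n_null=380, n_planted=20, delta=0.6, n_per_class=30, seed=15)


@pytest.fixture(scope="module")
def separable_run(separable):
    matrix, labels, _ = separable
    return backward_elimination_cv(matrix, labels, SMALL)


def test_halving_schedule_full_protocol():
    expected = [10000, 5000, 2500, 1250, 625, 313, 157, 79, 40, 20, 10, 5, 3, 2, 1]
    assert halving_schedule(10000, 15) == expected


@pytest.mark.parametrize(
    "n_start, n_steps, expected",
    [(8, 4, [8, 4, 2, 1]), (7, 4, [7, 4, 2, 1]), (2, 2, [2, 1])],
)
def test_halving_schedule_small(n_start, n_steps, expected):
    assert halving_schedule(n_start, n_steps) == expected


def test_halving_schedule_degenerate_clamps_with_warning():
    with pytest.warns(UserWarning, match="truncated"):
        assert halving_schedule(1, 3) == [1]


def test_schedule_properties():
    for n_start in (1, 3, 17, 4096, 9999):
        s = halving_schedule(n_start, 15)
        assert s[0] == min(n_start, s[0]) and s[-1] >= 1
        assert all(b == max(1, -(-a // 2)) for a, b in zip(s, s[1:]))
        assert all(a > b for a, b in zip(s, s[1:]))


def test_separable_accuracy_and_nesting(separable_run):
    result = separable_run
    # strong planted signal: perfect held-out accuracy down to ~10 features
    acc = result.accuracy_frame()
    assert (acc.loc[acc.n_features >= 10, "accuracy"] == 1.0).all()
    # single-feature final model still valid
    assert set(acc.n_features) == set(result.schedule)
    final = acc[acc.n_features == 1]
    assert ((final.accuracy >= 0) & (final.accuracy <= 1)).all()
    # strict nesting of feature sets within each (repeat, fold)
    by_fold: dict = {}
    for r in result.records:
        by_fold.setdefault((r.repeat, r.fold), []).append(r)
    for models in by_fold.values():
        models.sort(key=lambda r: r.step)
        for a, b in zip(models, models[1:]):
            assert set(b.features) < set(a.features)


def test_separable_beats_nearest_centroid_oracle(separable, separable_run):
    """An independent nearest-centroid classifier confirms separability."""
    matrix, labels, _ = separable
    X = matrix.beta.to_numpy().T
    y = labels.to_numpy()
    cents = {c: X[y == c].mean(axis=0) for c in np.unique(y)}
    pred = [min(cents, key=lambda c: ((x - cents[c]) ** 2).sum()) for x in X]
    assert (pred == y).mean() == 1.0
    assert separable_run.median_accuracy(19) == 1.0


def test_no_leakage_from_test_fold(separable):
    """A probe informative only among one fold's samples is never selected
    when that fold is held out (feature ranking sees training data only)."""
    matrix, labels, _ = separable
    cfg = SelectionConfig(n_start=100, n_steps=5, n_trees=50, n_repeats=1, seed=11)
    base = backward_elimination_cv(matrix, labels, cfg)
    test_samples = base.fold_assignment[(0, 0)]
    beta = matrix.beta.copy()
    leak = pd.Series(0.5, index=beta.columns)
    leak[test_samples] = [0.95 if labels[s] == "A" else 0.05 for s in test_samples]
    beta.loc["cg_leak"] = leak
    rerun = backward_elimination_cv(MethylationMatrix(beta), labels, cfg)
    assert rerun.fold_assignment[(0, 0)] == test_samples  # same seeded folds
    for r in rerun.records:
        if r.fold == 0:
            assert "cg_leak" not in r.features


def test_fixed_seed_bit_identical(separable):
    matrix, labels, _ = separable
    cfg = SelectionConfig(n_start=100, n_steps=4, n_trees=50, n_repeats=1, seed=5)
    r1 = backward_elimination_cv(matrix, labels, cfg)
    r2 = backward_elimination_cv(matrix, labels, cfg)
    pd.testing.assert_frame_equal(r1.accuracy_frame(), r2.accuracy_frame())
    for a, b in zip(r1.records, r2.records):
        assert a.features == b.features
        pd.testing.assert_series_equal(a.importances, b.importances)


def test_permutation_null_near_chance(separable):
    matrix, labels, _ = separable
    cfg = SelectionConfig(n_start=50, n_steps=3, n_trees=50, n_repeats=6, seed=3)
    null = permutation_null(matrix, labels, cfg)
    acc = null.accuracy_frame()
    per_repeat = acc.groupby("repeat")["accuracy"].mean()
    se = per_repeat.std(ddof=1) / np.sqrt(len(per_repeat))
    assert abs(per_repeat.mean() - 0.5) < max(3 * se, 0.1)
    # the real run dominates the null on a separable fixture
    real = backward_elimination_cv(matrix, labels, cfg)
    assert real.accuracy_frame()["accuracy"].median() > acc["accuracy"].median()


def test_unbalanced_null_tracks_majority_share():
    matrix, labels, _ = two_class_matrix(n_null=60, n_planted=5, delta=0.5, n_per_class=20, seed=33)
    # make it 32 vs 8: relabel the last 12 'B' samples as 'A'
    lab = labels.copy()
    lab.iloc[28:] = "A"
    cfg = SelectionConfig(n_start=30, n_steps=2, n_trees=100, n_repeats=6, seed=9)
    null = permutation_null(matrix, lab, cfg)
    mean_acc = null.accuracy_frame()["accuracy"].mean()
    assert abs(mean_acc - 0.8) < 0.12  # majority share 32/40


def test_aggregate_importance_recovers_planted(separable, separable_run):
    _, _, planted = separable
    imp = aggregate_importance(separable_run, min_features=20)
    assert set(imp.index[:10]) <= set(planted)
    with pytest.raises(ValueError, match="no qualifying models"):
        aggregate_importance(separable_run, min_features=10**6)
    # deterministic under the fixed seed
    imp2 = aggregate_importance(separable_run, min_features=20)
    pd.testing.assert_series_equal(imp, imp2)


def test_performance_summary_arithmetic():
    """TP=9 FN=1 TN=8 FP=2 -> sensitivity 0.9, specificity 0.8."""
    y_true = np.array(["A"] * 10 + ["B"] * 10)
    y_pred = np.array(["A"] * 9 + ["B"] + ["B"] * 8 + ["A"] * 2)
    rec = ModelRecord(
        repeat=0, fold=0, step=0, n_features=5, features=("x",),
        accuracy=float((y_true == y_pred).mean()),
        y_true=y_true, y_pred=y_pred,
        importances=pd.Series([1.0], index=["x"]),
    )
    from brainmeth.rf_selection import SelectionResult

    result = SelectionResult(
        config=SelectionConfig(n_start=5, n_steps=1, n_trees=1, n_repeats=1),
        schedule=[5], classes=["A", "B"], records=[rec],
    )
    summary = performance_summary(result).set_index("class")
    assert summary.loc["A", "mean_sensitivity"] == pytest.approx(0.9)
    assert summary.loc["A", "mean_specificity"] == pytest.approx(0.8)
    assert summary.loc["B", "mean_sensitivity"] == pytest.approx(0.8)
    assert summary.loc["B", "mean_specificity"] == pytest.approx(0.9)


def test_performance_summary_perfect_and_degenerate(separable_run):
    summary = performance_summary(separable_run, min_features=20).set_index("class")
    assert (summary["mean_sensitivity"] == 1.0).all()
    assert (summary["mean_specificity"] == 1.0).all()
    # an all-one-class predictor: that class sens 1, the other 0
    y_true = np.array(["A", "A", "B", "B"])
    y_pred = np.array(["A", "A", "A", "A"])
    rec = ModelRecord(
        repeat=0, fold=0, step=0, n_features=2, features=("x",), accuracy=0.5,
        y_true=y_true, y_pred=y_pred, importances=pd.Series([1.0], index=["x"]),
    )
    from brainmeth.rf_selection import SelectionResult

    res = SelectionResult(
        config=SelectionConfig(n_start=2, n_steps=1, n_trees=1, n_repeats=1),
        schedule=[2], classes=["A", "B"], records=[rec],
    )
    s = performance_summary(res).set_index("class")
    assert s.loc["A", "mean_sensitivity"] == 1.0
    assert s.loc["B", "mean_sensitivity"] == 0.0


def test_class_smaller_than_folds_errors(separable):
    matrix, labels, _ = separable
    lab = labels.copy()
    lab[:] = "A"
    lab.iloc[0] = "B"
    with pytest.raises(ValueError, match="smaller than n_folds"):
        backward_elimination_cv(matrix, lab, SMALL)


def test_missing_beta_errors(separable):
    matrix, labels, _ = separable
    beta = matrix.beta.copy()
    beta.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        backward_elimination_cv(MethylationMatrix(beta), labels, SMALL)
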