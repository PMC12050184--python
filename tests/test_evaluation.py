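"""ROC/AUC, Youden thresholds, confusion matrices and cross-validation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radshape import (TrainConfig, ValidationError, confusion_matrix,
                      cross_validate, roc_auc, stratified_kfold,
                      youden_threshold)


def pair_count_auc(scores, labels):
    """Exhaustive pair-counting oracle: wins + half-ties over all pairs."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def test_auc_trivial_cases():
    assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
    assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5
    assert roc_auc([0.9, 0.4, 0.8, 0.3], [1, 1, 0, 0]) == 0.75
    with pytest.raises(ValidationError):
        roc_auc([0.1, 0.2], [1, 1])


@pytest.mark.parametrize("seed", range(10))
def test_auc_equals_pair_counting_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 200))
    scores = np.round(rng.uniform(0, 1, n), 2)   # rounding induces ties
    labels = rng.integers(0, 2, n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    assert roc_auc(scores, labels) == pytest.approx(
        pair_count_auc(scores, labels), abs=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-10, 10), min_size=4, max_size=30),
       st.integers(0, 2 ** 31 - 1))
def test_auc_invariant_under_monotone_transform(scores, seed):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, len(scores))
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    s = np.round(np.asarray(scores), 6)   # keep exp strictly monotone in floats
    assert roc_auc(np.exp(s / 5), labels) == pytest.approx(
        roc_auc(s, labels), abs=1e-12)


def test_youden_separated_midpoint():
    scores = [0.8, 0.9, 0.95, 0.1, 0.2]
    labels = [1, 1, 1, 0, 0]
    assert youden_threshold(scores, labels) == pytest.approx(0.5)


def test_youden_tie_resolves_to_lowest_threshold():
    """J is maximized (0.5) at midpoints 0.225 and 0.6; the lower wins."""
    assert youden_threshold([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == \
        pytest.approx(0.225)


def test_youden_two_point_degenerate():
    assert youden_threshold([0.8, 0.2], [1, 0]) == pytest.approx(0.5)
    with pytest.raises(ValidationError):
        youden_threshold([0.8, 0.2], [1, 1])


@pytest.mark.parametrize("seed", range(5))
def test_youden_matches_exhaustive_scan(seed):
    rng = np.random.default_rng(seed)
    scores = rng.uniform(0, 1, 30)
    labels = rng.integers(0, 2, 30)
    labels[:2] = [0, 1]
    t = youden_threshold(scores, labels)
    y = labels.astype(bool)

    def j(th):
        pred = scores > th
        return (pred & y).sum() / y.sum() + \
            ((~pred) & ~y).sum() / (~y).sum() - 1
    uniq = np.unique(scores)
    cands = (uniq[:-1] + uniq[1:]) / 2
    best = max(j(c) for c in cands)
    assert j(t) == pytest.approx(best, abs=1e-12)
    assert t == pytest.approx(min(c for c in cands
                                  if j(c) == pytest.approx(best)), abs=1e-12)


def test_confusion_matrix_basics():
    classes = ["a", "b"]
    mat = confusion_matrix(["a", "a", "b", "b"], ["a", "b", "b", "b"], classes)
    np.testing.assert_array_equal(mat, [[1, 1], [0, 2]])
    assert np.trace(mat) / mat.sum() == 0.75
    perfect = confusion_matrix(["a", "b"], ["a", "b"], classes)
    assert np.trace(perfect) == perfect.sum()
    with pytest.raises(ValidationError):
        confusion_matrix([], [], classes)
    with pytest.raises(ValidationError):
        confusion_matrix(["a"], ["z"], classes)


def test_confusion_accuracy_equals_elementwise_mean(rng):
    classes = list("abc")
    truth = rng.choice(classes, 50)
    pred = rng.choice(classes, 50)
    mat = confusion_matrix(truth, pred, classes)
    assert np.trace(mat) / mat.sum() == np.mean(truth == pred)
    # row sums = per-class true counts
    for i, c in enumerate(classes):
        assert mat[i].sum() == np.sum(truth == c)


def test_stratified_kfold_cohort_composition():
    """43/17/12/8 over 4 folds -> every fold has 20 with per-class balance."""
    labels = (["normal"] * 43 + ["colles"] * 17 + ["barton"] * 12
              + ["smith"] * 8)
    folds = stratified_kfold(labels, k=4, seed=0)
    sizes = np.bincount(folds)
    np.testing.assert_array_equal(sizes, [20, 20, 20, 20])
    labels = np.asarray(labels)
    for cls, n in (("normal", 43), ("colles", 17), ("barton", 12),
                   ("smith", 8)):
        counts = np.bincount(folds[labels == cls], minlength=4)
        assert counts.sum() == n
        assert counts.max() - counts.min() <= 1
    assert np.array_equal(folds, stratified_kfold(labels, k=4, seed=0))
    assert not np.array_equal(folds, stratified_kfold(labels, k=4, seed=1))


def test_stratified_kfold_small_class_round_robin():
    folds = stratified_kfold(["s"] * 8, k=4, seed=2)
    np.testing.assert_array_equal(np.bincount(folds), [2, 2, 2, 2])
    with pytest.raises(ValidationError):
        stratified_kfold(["s"] * 8, k=1)
    with pytest.raises(ValidationError):
        stratified_kfold(["s"] * 8, k=9)


def test_folds_partition_dataset(rng):
    labels = rng.choice(["a", "b", "c"], 37)
    folds = stratified_kfold(labels, k=5, seed=3)
    assert folds.min() >= 0 and folds.max() < 5 and len(folds) == 37


def test_auc_against_sklearn_oracle(rng):
    from sklearn.metrics import roc_auc_score
    for _ in range(10):
        scores = np.round(rng.uniform(0, 1, 60), 2)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


def _quick_config(seed=0):
    return TrainConfig(max_epochs=150, seed=seed)


def test_cross_validate_structure(rng):
    n = 48
    labels = (["normal"] * 20 + ["barton"] * 12 + ["colles"] * 8
              + ["smith"] * 8)
    x = rng.normal(size=(n, 6))
    x[:20, 0] += 4      # separable signal for one class
    reports = cross_validate(x, labels, feature_counts=[3, 6], k=4, seed=0,
                             train_config=_quick_config())
    assert set(reports) == {3, 6}
    rep = reports[6]
    assert rep.auc.shape == (4, 5)              # 4 folds x (4 classes + Mean)
    assert rep.thresholds.shape == (4, 4)
    assert len(rep.accuracies) == len(rep.confusions) == 4
    for fold, mat in enumerate(rep.confusions):
        test_counts = np.asarray(mat).sum(axis=1)
        assert test_counts.sum() == 12           # fold size
    assert 0 <= rep.mean_accuracy <= 1
    with pytest.raises(ValidationError):
        cross_validate(x, labels, feature_counts=[7], k=4, seed=0,
                       train_config=_quick_config())


def test_cross_validate_no_signal_auc_near_half(rng):
    """Pure-noise features: mean held-out one-vs-rest AUC ~ 0.5 (the
    training AUC exceeds 0.5 through overfitting, so the null shows on the
    test folds)."""
    labels = (["normal"] * 16 + ["barton"] * 12 + ["colles"] * 10
              + ["smith"] * 10)
    aucs = []
    for seed in range(10):
        x = np.random.default_rng(seed).normal(size=(48, 4))
        rep = cross_validate(x, labels, feature_counts=[4], k=4, seed=seed,
                             train_config=_quick_config(seed))[4]
        aucs.append(rep.mean_test_auc)
    assert abs(np.mean(aucs) - 0.5) < 0.1
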