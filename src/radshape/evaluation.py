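"""Classifier evaluation: ROC/AUC, threshold selection, stratified k-fold
cross-validation and confusion-matrix reports.

AUC uses the rank (pair-counting) definition — the probability that a
random positive outscores a random negative, ties counted one half.
Per-class operating thresholds maximize Youden's J (sensitivity +
specificity - 1) over midpoints of adjacent sorted unique scores; by
default they are selected on the TRAINING folds so the held-out fold stays
untouched.  A ``leaky_thresholds`` switch reproduces the simpler protocol
of picking thresholds on the test fold, for comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import nn
from .errors import ValidationError


def roc_auc(scores, labels) -> float:
    """Pair-counting AUC (Mann-Whitney); ties contribute one half."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores/labels must be matching 1-D arrays")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes present")
    ranks = rankdata(s)            # average ranks handle ties as half-wins
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def youden_threshold(scores, labels) -> float:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Candidates are midpoints of adjacent sorted unique scores (prediction
    rule: positive iff score > threshold).  Ties in J resolve to the lowest
    threshold.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("threshold selection needs both classes")
    uniq = np.unique(s)
    if len(uniq) < 2:
        raise ValidationError("all scores identical; no threshold separates")
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    best_t, best_j = None, -np.inf
    for t in cands:                      # ascending, so first max wins
        pred = s > t
        sens = np.sum(pred & y) / n_pos
        spec = np.sum(~pred & ~y) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-15:
            best_j, best_t = j, float(t)
    return best_t


def confusion_matrix(true_labels, pred_labels, classes) -> np.ndarray:
    """Entry (i, j) = count of true class i predicted as class j."""
    classes = list(classes)
    true_labels = list(true_labels)
    pred_labels = list(pred_labels)
    if not true_labels:
        raise ValidationError("empty label lists")
    if len(true_labels) != len(pred_labels):
        raise ValidationError("label list length mismatch")
    index = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(true_labels, pred_labels):
        if t not in index or p not in index:
            raise ValidationError(f"label outside class order: {t!r}/{p!r}")
        mat[index[t], index[p]] += 1
    return mat


def stratified_kfold(labels, k: int, seed: int = 0) -> np.ndarray:
    """Seeded stratified fold assignment (values 0..k-1 per sample).

    Within each class, shuffled members are dealt round-robin; the fold
    receiving each class's remainder rotates across classes so total fold
    sizes stay balanced.  Classes with fewer than k members still spread
    round-robin (e.g. 8 members over 4 folds -> 2 per fold).
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2 or k > n:
        raise ValidationError(f"k must satisfy 2 <= k <= N (got k={k}, N={n})")
    rng = np.random.default_rng(seed)
    folds = np.full(n, -1, dtype=np.int64)
    offset = 0
    for cls in dict.fromkeys(labels.tolist()):   # deterministic class order
        idx = np.nonzero(labels == cls)[0]
        idx = idx[rng.permutation(len(idx))]
        assign = (np.arange(len(idx)) + offset) % k
        folds[idx] = assign
        offset = (offset + len(idx)) % k
    return folds


@dataclass
class CrossValReport:
    """Per-fold results for one feature count (the Tables 3-5 layout)."""

    feature_count: int
    classes: tuple
    auc: pd.DataFrame                 # rows k_1..k_k, columns = classes + Mean
    thresholds: pd.DataFrame          # same rows, columns = classes
    accuracies: list = field(default_factory=list)
    confusions: list = field(default_factory=list)
    test_auc: Optional[pd.DataFrame] = None   # held-out one-vs-rest AUC

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def mean_auc(self) -> float:
        """Mean one-vs-rest AUC on the training folds (report layout)."""
        return float(self.auc["Mean"].mean())

    @property
    def mean_test_auc(self) -> float:
        return float(self.test_auc["Mean"].mean())

    @property
    def mean_thresholds(self) -> pd.Series:
        return self.thresholds.mean(axis=0)


def cross_validate(features: np.ndarray, labels: Sequence[str],
                   feature_counts: Sequence[int] = (5, 10, 15),
                   k: int = 4, seed: int = 0,
                   train_config: Optional[nn.TrainConfig] = None,
                   classes: Sequence[str] = nn.DEFAULT_CLASSES,
                   hidden_size: int = 10,
                   leaky_thresholds: bool = False) -> dict:
    """Stratified k-fold CV of the sigmoid network for each feature count.

    ``features`` holds already-standardized mode coefficients, one row per
    subject, with at least ``max(feature_counts)`` columns.  For each fold:
    train on the other k-1 folds using the first F features, record one-vs-
    rest training AUC and a Youden threshold per class (on training scores
    unless ``leaky_thresholds``), then the held-out accuracy and confusion
    matrix.  Returns ``{F: CrossValReport}``.
    """
    x = np.atleast_2d(np.asarray(features, np.float64))
    labels = list(labels)
    classes = tuple(classes)
    if max(feature_counts) > x.shape[1]:
        raise ValidationError(
            f"feature count {max(feature_counts)} exceeds available "
            f"components ({x.shape[1]})")
    base_config = train_config or nn.TrainConfig()
    y = nn.one_hot(labels, classes)
    folds = stratified_kfold(labels, k, seed)
    reports = {}
    for f_count in feature_counts:
        auc_rows, thr_rows, test_rows, accs, confs = [], [], [], [], []
        for fold in range(k):
            test = folds == fold
            train = ~test
            cfg = nn.TrainConfig(
                learning_rate=base_config.learning_rate,
                max_epochs=base_config.max_epochs,
                batch_size=base_config.batch_size,
                tol=base_config.tol,
                seed=int(np.random.default_rng(
                    [base_config.seed, fold, f_count]).integers(2 ** 31)),
                loss_kind=base_config.loss_kind)
            model = nn.init_classifier(f_count, hidden_size, classes,
                                       seed=cfg.seed)
            model, _ = nn.train_sgd(model, x[train, :f_count], y[train], cfg)
            p_train = nn.forward(model, x[train, :f_count])
            p_test = nn.forward(model, x[test, :f_count])
            auc_row, thr_row, test_row = {}, {}, {}
            for ci, cname in enumerate(classes):
                auc_row[cname] = roc_auc(p_train[:, ci], y[train][:, ci])
                yt = y[test][:, ci]
                test_row[cname] = (roc_auc(p_test[:, ci], yt)
                                   if 0 < yt.sum() < len(yt) else np.nan)
                sel_p, sel_y = ((p_test[:, ci], y[test][:, ci])
                                if leaky_thresholds
                                else (p_train[:, ci], y[train][:, ci]))
                thr_row[cname] = youden_threshold(sel_p, sel_y)
            auc_row["Mean"] = float(np.mean(list(auc_row.values())))
            test_row["Mean"] = float(np.nanmean(list(test_row.values())))
            auc_rows.append(auc_row)
            thr_rows.append(thr_row)
            test_rows.append(test_row)
            pred, _, _ = nn.predict(model, x[test, :f_count])
            truth = [labels[i] for i in np.nonzero(test)[0]]
            mat = confusion_matrix(truth, pred, classes)
            confs.append(mat)
            accs.append(float(np.trace(mat) / mat.sum()))
        idx = [f"k_{i + 1}" for i in range(k)]
        reports[f_count] = CrossValReport(
            feature_count=f_count, classes=classes,
            auc=pd.DataFrame(auc_rows, index=idx),
            thresholds=pd.DataFrame(thr_rows, index=idx),
            accuracies=accs, confusions=confs,
            test_auc=pd.DataFrame(test_rows, index=idx))
    return reports
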