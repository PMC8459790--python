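"""Cross-validation drivers and performance metrics.

Binary metrics follow the usual confusion-matrix definitions relative to
a declared positive label: accuracy, sensitivity (TPR), specificity
(TNR), false-positive rate, and positive/negative predictive values.
Ratios with a zero denominator are reported as ``None`` (undefined)
rather than propagating NaN.  AUC is computed by the rank (Mann-Whitney)
formulation with midranks for ties, which equals the trapezoidal area
under the ROC curve; the positive-class score of the ensemble is its
vote fraction for the positive label.  Multi-class runs report the full
confusion matrix instead of ROC.

Cross-validation re-runs the entire fit (bootstraps, filtering and
clustering included) inside every training fold by default, so no
information from held-out samples reaches feature selection.  A
permissive mode that selects features once on the full data and only
retrains the base learners per fold is available for comparison.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import (
    KFold,
    LeaveOneOut,
    StratifiedKFold,
    StratifiedShuffleSplit,
)

from .data_io import ExpressionDataset, RunConfig
from .ensemble import EnsembleModel, fit, majority_vote, predict
from .sac import project

__all__ = [
    "MetricsReport",
    "confusion_metrics",
    "confusion_counts",
    "multiclass_confusion",
    "roc_auc",
    "kfold_eval",
    "random_split_eval",
]


@dataclass
class MetricsReport:
    """Binary classification ratios; ``None`` marks an undefined ratio."""

    acc: float | None
    sensitivity: float | None
    specificity: float | None
    fpr: float | None
    ppv: float | None
    npv: float | None
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def confusion_counts(y_true, y_pred, positive_label) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) relative to the declared positive label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    tp = int(np.sum(pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    return tp, tn, fp, fn


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def confusion_metrics(y_true, y_pred, positive_label) -> MetricsReport:
    """Acc, SN, SP, FPR, PPV, NPV from predictions, one-vs-rest on the
    positive label."""
    tp, tn, fp, fn = confusion_counts(y_true, y_pred, positive_label)
    return MetricsReport(
        acc=_ratio(tp + tn, tp + fp + tn + fn),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        fpr=_ratio(fp, fp + tn),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        tp=tp, tn=tn, fp=fp, fn=fn,
    )


def multiclass_confusion(y_true, y_pred, labels: list) -> np.ndarray:
    """N x N confusion matrix with rows = truth, in the given label order."""
    return _sk_confusion(y_true, y_pred, labels=list(labels))


def roc_auc(y_true, positive_scores, positive_label) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic
    (midranks for tied scores)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(positive_scores, dtype=float)
    if len(y_true) != len(scores):
        raise ValueError("labels and scores must have equal length")
    pos = y_true == positive_label
    n_pos = int(pos.sum())
    n_neg = int(len(y_true) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class CVResult:
    """Per-fold (or per-run) accuracies with summary statistics."""

    fold_accuracies: list[float]
    mean_accuracy: float
    confusion: np.ndarray | None
    label_order: list

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": self.fold_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "confusion": None if self.confusion is None else self.confusion.tolist(),
            "label_order": [str(l) for l in self.label_order],
        }


def _derived_seed(seed: int, i: int) -> int:
    return (seed + 7919 * (i + 1)) % (2**31)


def _check_stratifiable(ds: ExpressionDataset, k: int) -> None:
    _, counts = np.unique(ds.classes, return_counts=True)
    if counts.min() < 2:
        raise ValueError("stratified folding requires >= 2 members per class")
    if counts.min() < k:
        raise ValueError(
            f"stratified {k}-fold requires every class to have >= {k} members"
        )


def kfold_eval(ds: ExpressionDataset, cfg: RunConfig, k: int, seed: int = 0,
               stratified: bool = True, mode: str = "refit") -> CVResult:
    """k-fold cross-validation of the full pipeline (k = U gives LOOCV).

    ``mode="refit"`` re-runs feature selection inside every training
    fold; ``mode="preselect"`` fixes the reduced sub-datasets once on the
    full data and only retrains base learners per fold.
    """
    if k < 2 or k > ds.n_samples:
        raise ValueError(f"k={k} must be in 2..{ds.n_samples}")
    if mode not in ("refit", "preselect"):
        raise ValueError("mode must be 'refit' or 'preselect'")
    if k == ds.n_samples:
        splitter = LeaveOneOut()
        splits = splitter.split(ds.values)
    elif stratified:
        _check_stratifiable(ds, k)
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(ds.values, ds.classes)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(ds.values)

    label_order = ds.label_order
    full_model = None
    if mode == "preselect":
        full_model = fit(ds, dataclasses.replace(cfg, seed=_derived_seed(seed, -1)))

    accs: list[float] = []
    pooled = np.zeros((len(label_order), len(label_order)), dtype=int)
    for i, (train_idx, test_idx) in enumerate(splits):
        y_test = ds.classes[test_idx]
        if mode == "refit":
            sub = ds.subset(train_idx)
            model = fit(sub, dataclasses.replace(cfg, seed=_derived_seed(seed, i)))
            preds = predict(model, ds.values[test_idx])
        else:
            preds = _preselect_predict(full_model, ds, train_idx, test_idx)
        accs.append(float(np.mean(preds == y_test)))
        pooled += multiclass_confusion(y_test, preds, label_order)
    return CVResult(
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        confusion=pooled,
        label_order=label_order,
    )


def _preselect_predict(full_model: EnsembleModel, ds: ExpressionDataset,
                       train_idx, test_idx) -> np.ndarray:
    from .ensemble import make_learner  # local to avoid cycle at import time

    votes = np.empty((len(test_idx), full_model.n_base_models), dtype=object)
    for b, bm in enumerate(full_model.base_models):
        F_train = project(bm.rsd, ds.values[train_idx])
        F_test = project(bm.rsd, ds.values[test_idx])
        learner = make_learner(full_model.config, seed=full_model.config.seed + b)
        learner.fit(F_train, ds.classes[train_idx])
        votes[:, b] = learner.predict(F_test)
    return majority_vote(votes, full_model.label_order)


@dataclass
class RandomSplitResult:
    accuracies: list[float]
    best: float
    mean: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def random_split_eval(ds: ExpressionDataset, cfg: RunConfig, n_runs: int = 50,
                      seed: int = 0) -> RandomSplitResult:
    """Repeated stratified 2/3 train, 1/3 test splits; the full pipeline
    is re-fitted on each training split.  Reports all run accuracies plus
    best and mean (never the best alone)."""
    if ds.n_samples < 6:
        raise ValueError("random splitting requires at least 6 samples")
    splitter = StratifiedShuffleSplit(n_splits=n_runs, test_size=1 / 3, random_state=seed)
    accs: list[float] = []
    for i, (train_idx, test_idx) in enumerate(splitter.split(ds.values, ds.classes)):
        sub = ds.subset(train_idx)
        model = fit(sub, dataclasses.replace(cfg, seed=_derived_seed(seed, i)))
        preds = predict(model, ds.values[test_idx])
        accs.append(float(np.mean(preds == ds.classes[test_idx])))
    return RandomSplitResult(accuracies=accs, best=max(accs), mean=float(np.mean(accs)))
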