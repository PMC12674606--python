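"""Metrics, repeated stratified cross-validation, paired model comparison.

Binary classification is summarized by accuracy, F1 for a designated positive
class, the Matthews correlation coefficient (MCC, with the zero-marginal
convention MCC = 0), and AUC computed as the Mann–Whitney probability that a
random positive outscores a random negative with ties counted 1/2.

Model evaluation follows repeated stratified k-fold cross-validation
(default 10 × 5-fold); paired comparison between two models run on identical
fold assignments uses the two-sided Wilcoxon signed-rank test on per-fold
metric differences (a paired t-test is available via flag).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata, ttest_rel, wilcoxon
from sklearn.model_selection import StratifiedKFold

from .preprocess import ExpressionMatrix, LabelVector

logger = logging.getLogger("rpslearner")

METRIC_NAMES = ("accuracy", "f1", "mcc", "auc")


@dataclass
class MetricSet:
    accuracy: float
    f1: float
    mcc: float
    auc: float  # NaN when undefined (single-class truth)
    fold_id: int = 0
    repeat_id: int = 0

    def get(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise ValueError(f"unknown metric {name!r}; choose from {METRIC_NAMES}")
        return getattr(self, name)


def compute_metrics(
    y_true,
    y_pred,
    y_score=None,
    positive_class=None,
    average: str = "binary",
    fold_id: int = 0,
    repeat_id: int = 0,
) -> MetricSet:
    """Accuracy, F1, MCC and AUC for one evaluation fold.

    ``y_score`` holds positive-class scores (any monotone score works for
    AUC).  ``average="binary"`` (default) computes F1 for ``positive_class``;
    ``average="macro"`` averages per-class F1 over all classes.
    """
    if isinstance(y_true, LabelVector):
        if positive_class is None:
            positive_class = y_true.positive_class
        y_true = y_true.labels
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} truths, {len(y_pred)} predictions")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    if positive_class is None:
        positive_class = classes[-1]
    positive_class = np.asarray([positive_class], dtype=y_true.dtype)[0]

    acc = float(np.mean(y_true == y_pred))

    if average == "macro":
        f1 = float(np.mean([_f1_one(y_true, y_pred, c) for c in classes]))
    else:
        f1 = _f1_one(y_true, y_pred, positive_class)

    mcc = _mcc_binary(y_true, y_pred, positive_class)

    if y_score is None:
        auc = np.nan
    else:
        y_score = np.asarray(y_score, dtype=float)
        if len(y_score) != len(y_true):
            raise ValueError("y_score length mismatch")
        auc = _auc_mann_whitney(y_true == positive_class, y_score)
    return MetricSet(acc, f1, mcc, auc, fold_id=fold_id, repeat_id=repeat_id)


def _f1_one(y_true, y_pred, cls) -> float:
    tp = np.sum((y_pred == cls) & (y_true == cls))
    fp = np.sum((y_pred == cls) & (y_true != cls))
    fn = np.sum((y_pred != cls) & (y_true == cls))
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom else 0.0


def _mcc_binary(y_true, y_pred, positive) -> float:
    """Closed-form MCC from the 2x2 confusion matrix; 0 when any marginal is zero."""
    t = y_true == positive
    p = y_pred == positive
    tp = float(np.sum(t & p))
    tn = float(np.sum(~t & ~p))
    fp = float(np.sum(~t & p))
    fn = float(np.sum(t & ~p))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def _auc_mann_whitney(is_pos: np.ndarray, scores: np.ndarray) -> float:
    """P(random positive outscores random negative), ties as 1/2, via ranks."""
    n_pos = int(is_pos.sum())
    n_neg = len(is_pos) - n_pos
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined for single-class truth; returning NaN")
        return np.nan
    ranks = rankdata(scores)  # midranks handle ties as 1/2
    u = ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


# -------------------------------------------------------- cross-validation


@dataclass
class CVResult:
    """repeats × folds MetricSets plus the fold assignments that produced them.

    ``fold_assignments[r][i]`` is the test-fold index of sample i in repeat r,
    cached so that comparator runs can be truly paired.
    """

    metrics: list[MetricSet]
    fold_assignments: list[np.ndarray]
    repeats: int
    folds: int
    seed: int
    config: dict = field(default_factory=dict)

    def mean(self, name: str) -> float:
        vals = [m.get(name) for m in self.metrics]
        return float(np.nanmean(vals))

    def values(self, name: str) -> np.ndarray:
        """Per-fold values in (repeat, fold) order."""
        return np.array([m.get(name) for m in self.metrics])

    def summary(self) -> dict:
        return {
            name: {"mean": self.mean(name), "sd": float(np.nanstd(self.values(name), ddof=1))}
            for name in METRIC_NAMES
        }


def repeated_stratified_cv(
    X,
    y: LabelVector,
    trainer,
    repeats: int = 10,
    folds: int = 5,
    seed: int = 0,
    config: dict | None = None,
) -> CVResult:
    """Repeated stratified k-fold evaluation of a fit/predict pair.

    ``trainer(X_train, y_train, X_test, fold_seed)`` must return
    ``(predicted_labels, positive_class_scores)`` for the test rows; all
    preprocessing, projection and model fitting happen inside the trainer on
    the training side only.  Each repeat uses an independent stratified
    partition seeded ``seed + repeat``.
    """
    y_arr = np.asarray(y.labels)
    counts = np.bincount(y.as_int(), minlength=y.n_classes)
    if counts.min() < folds:
        raise ValueError(
            f"stratification impossible: smallest class has {counts.min()} < folds={folds}"
        )
    n = len(y)
    is_em = isinstance(X, ExpressionMatrix)
    X_arr = X if is_em else np.asarray(X, dtype=float)

    metrics: list[MetricSet] = []
    assignments: list[np.ndarray] = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        fold_of = np.full(n, -1, dtype=int)
        for f, (tr, te) in enumerate(skf.split(np.zeros((n, 1)), y_arr)):
            fold_of[te] = f
            Xtr = X_arr.subset_rows(tr) if is_em else X_arr[tr]
            Xte = X_arr.subset_rows(te) if is_em else X_arr[te]
            ytr = LabelVector(
                labels=list(y_arr[tr]),
                label_set=y.label_set,
                positive_class=y.positive_class,
            )
            pred, score = trainer(Xtr, ytr, Xte, seed + 1000 * r + f)
            metrics.append(
                compute_metrics(
                    y_arr[te],
                    np.asarray(pred),
                    score,
                    positive_class=y.positive_class,
                    fold_id=f,
                    repeat_id=r,
                )
            )
        assignments.append(fold_of)
    return CVResult(
        metrics=metrics,
        fold_assignments=assignments,
        repeats=repeats,
        folds=folds,
        seed=seed,
        config=config or {},
    )


# ------------------------------------------------------- paired comparison


def paired_comparison(a: CVResult, b: CVResult, metric: str = "accuracy", test: str = "wilcoxon") -> dict:
    """Two-sided paired test on per-fold metric differences b − a.

    Requires identical fold assignments (same seed/partition) so the folds
    are truly paired.  Returns median difference, direction, and p-value.
    All-zero differences give p = 1 by convention.
    """
    if a.repeats != b.repeats or a.folds != b.folds or a.seed != b.seed:
        raise ValueError("CV structures differ (repeats/folds/seed); folds are not paired")
    for fa, fb in zip(a.fold_assignments, b.fold_assignments):
        if not np.array_equal(fa, fb):
            raise ValueError("fold assignments differ; comparisons must share partitions")
    va, vb = a.values(metric), b.values(metric)
    diff = vb - va
    median = float(np.median(diff))
    if np.all(diff == 0):
        p = 1.0
    elif test == "wilcoxon":
        p = float(wilcoxon(vb, va, alternative="two-sided", zero_method="wilcox").pvalue)
    elif test == "ttest":
        p = float(ttest_rel(vb, va).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    direction = "b" if median > 0 else ("a" if median < 0 else "tie")
    return {
        "metric": metric,
        "median_difference": median,
        "mean_difference": float(np.mean(diff)),
        "p_value": p,
        "favors": direction,
        "test": test,
    }
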