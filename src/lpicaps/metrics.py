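"""Evaluation: confusion counts, threshold metrics, AUC/AUPRC and
stratified k-fold cross-validation.

Accuracy = (TP+TN)/(TP+TN+FP+FN), Precision = TP/(TP+FP),
Recall = TP/(TP+FN), F-value = 2PR/(P+R).  Zero-denominator ratios are
reported as 0.0 with an ``undefined`` flag rather than raising, so
ensemble sweeps never crash on a degenerate fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f_value: float
    auc: float | None = None
    auprc: float | None = None
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_value": self.f_value,
            "auc": self.auc,
            "auprc": self.auprc,
            "undefined": list(self.undefined),
        }


def confusion(scores, labels, threshold: float) -> ConfusionCounts:
    """Confusion counts under strict-greater-than thresholding, matching
    the classifier's decision rule."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError(
            f"scores shape {scores.shape} != labels shape {labels.shape}"
        )
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pred = scores > threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def metrics_from_confusion(c: ConfusionCounts) -> MetricsReport:
    if c.total == 0:
        raise ValueError("no samples")
    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    precision = ratio(c.tp, c.tp + c.fp, "precision")
    recall = ratio(c.tp, c.tp + c.fn, "recall")
    if precision + recall > 0:
        f_value = 2 * precision * recall / (precision + recall)
    else:
        undefined.append("f_value")
        f_value = 0.0
    return MetricsReport(
        accuracy=(c.tp + c.tn) / c.total,
        precision=precision,
        recall=recall,
        f_value=f_value,
        undefined=undefined,
    )


def auc_auprc(scores, labels) -> tuple[float, float]:
    """Trapezoidal ROC area and step-interpolated precision-recall area."""
    labels = np.asarray(labels)
    if len(set(np.unique(labels))) < 2:
        raise ValueError("both classes must be present to compute AUC/AUPRC")
    return (
        float(roc_auc_score(labels, scores)),
        float(average_precision_score(labels, scores)),
    )


def evaluate(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Full report: threshold metrics plus AUC/AUPRC when both classes
    are present."""
    report = metrics_from_confusion(confusion(scores, labels, threshold))
    labels = np.asarray(labels)
    if len(set(np.unique(labels))) == 2:
        report.auc, report.auprc = auc_auprc(scores, labels)
    return report


def cross_validate(
    X: dict[str, np.ndarray],
    y,
    k: int,
    trainer,
    seed: int = 0,
    threshold: float = 0.5,
) -> dict:
    """Stratified k-fold cross-validation.

    ``trainer(X_train, y_train, seed)`` must return an object with a
    ``predict_scores(X)`` method.  Returns per-fold reports plus the mean
    and standard deviation of every metric.
    """
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    if int(np.sum(y == 1)) < k or int(np.sum(y == 0)) < k:
        raise ValueError(f"each class needs at least k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    dummy = np.zeros(len(y))
    for fold_id, (train_idx, test_idx) in enumerate(skf.split(dummy, y)):
        Xtr = {c: X[c][train_idx] for c in X}
        Xte = {c: X[c][test_idx] for c in X}
        model = trainer(Xtr, y[train_idx], seed + fold_id)
        scores = model.predict_scores(Xte)
        folds.append(evaluate(scores, y[test_idx], threshold))
    metric_names = ("accuracy", "precision", "recall", "f_value", "auc", "auprc")
    summary = {}
    for name in metric_names:
        vals = [getattr(f, name) for f in folds if getattr(f, name) is not None]
        if vals:
            summary[name] = {
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            }
    return {"folds": folds, "summary": summary}
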