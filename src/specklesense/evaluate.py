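"""Confusion matrices, binary detection metrics, and ROC/AUC reporting.

The five standard binary metrics are computed from the confusion counts with
"alcohol" as the positive class:

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)          (recall, true-positive rate)
    specificity = TN / (TN + FP)          (true-negative rate)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)

Zero denominators yield ``None`` (an explicit undefined marker) rather than
raising or silently returning 0.  Metrics are reported both at full
precision and rounded to integer percent (half-up).

Confusion-matrix orientation is rows = true labels, columns = predicted.
Reports also show the row-normalized percentage matrix, i.e. per-class
recall on the diagonal — often loosely called per-label "accuracy".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import ALCOHOL, NO_ALCOHOL, TrainedModel

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity", "f1")


def percent(x: float | None) -> int | None:
    """Round a fraction to integer percent, halves up; None passes through."""
    if x is None:
        return None
    return int(np.floor(100.0 * x + 0.5))


def metrics_from_counts(
    tp: int, fp: int, tn: int, fn: int
) -> dict[str, float | None]:
    """The five detection metrics from binary confusion counts.

    Any metric whose denominator is zero is returned as ``None``.  F1 is
    undefined when precision or sensitivity is undefined, or when both are 0.
    """
    counts = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
    for name, v in counts.items():
        if v < 0:
            raise ValueError(f"negative count {name}={v}")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("at least one count must be positive")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    precision = ratio(tp, tp + fp)
    sensitivity = ratio(tp, tp + fn)
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        f1 = None
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    return {
        "accuracy": (tp + tn) / total,
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": ratio(tn, tn + fp),
        "f1": f1,
    }


@dataclass
class ConfusionCounts:
    """Class-by-class confusion counts; rows are true labels, columns predicted."""

    classes: list[str]
    counts: np.ndarray  # (k, k) integer matrix

    @classmethod
    def from_pairs(
        cls, truth: Sequence[str], predicted: Sequence[str], classes: Sequence[str]
    ) -> "ConfusionCounts":
        if len(truth) != len(predicted):
            raise ValueError("truth and predicted must have equal length")
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(truth, predicted):
            counts[index[t], index[p]] += 1
        return cls(classes=list(classes), counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_percent(self) -> np.ndarray:
        """Row-normalized percentages (per-class recall on the diagonal)."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, 100.0 * self.counts / sums, np.nan)

    def binary_counts(
        self, positive: str = ALCOHOL, negative: str = NO_ALCOHOL
    ) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) for a binary scheme with the given positive class."""
        if set(self.classes) != {positive, negative}:
            raise ValueError(
                f"binary counts require classes {{{positive!r}, {negative!r}}}, "
                f"got {self.classes}"
            )
        p = self.classes.index(positive)
        n = self.classes.index(negative)
        tp = int(self.counts[p, p])
        fn = int(self.counts[p, n])
        tn = int(self.counts[n, n])
        fp = int(self.counts[n, p])
        return tp, fp, tn, fn


def roc_curve(
    scores: np.ndarray, truth: Sequence, positive_label=1
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points and AUC for a binary problem, threshold swept over scores.

    Returns (fpr, tpr, auc) with points ordered from the strictest threshold
    (0, 0) to the most permissive (1, 1); the AUC is the trapezoidal area.
    AUC is invariant under any strictly increasing transform of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([t == positive_label for t in truth])
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in truth")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    # keep the last point of each tied-score run
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass
class EvaluationReport:
    """Everything the study reports for one trained model on one validation set."""

    scheme_name: str
    confusion: ConfusionCounts
    metrics: dict[str, float | None]
    metrics_percent: dict[str, int | None]
    roc: dict[str, dict]  # per class: {"fpr": [...], "tpr": [...], "auc": float}
    auc_macro: float | None
    per_class_recall: dict[str, float | None]
    n_evaluated: int
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme_name,
            "classes": self.confusion.classes,
            "confusion_counts": self.confusion.counts.tolist(),
            "confusion_row_percent": np.round(self.confusion.row_percent(), 2).tolist(),
            "metrics": self.metrics,
            "metrics_percent": self.metrics_percent,
            "per_class_recall": self.per_class_recall,
            "roc": self.roc,
            "auc_macro": self.auc_macro,
            "n_evaluated": self.n_evaluated,
            "provenance": self.provenance,
        }


def evaluate_model(
    model: TrainedModel, validation: pd.DataFrame, provenance: dict | None = None
) -> EvaluationReport:
    """Predict on a validation table and assemble the full report.

    Binary schemes report the five detection metrics with "alcohol" as the
    positive class; all schemes report the confusion matrix, per-class
    recall, one-vs-rest ROC curves and the macro-average AUC.
    """
    from .classify import apply_scheme  # local import avoids a cycle at typing time

    truth = apply_scheme(validation["time_label"].tolist(), model.scheme)
    predicted = model.predict(validation)
    proba = model.predict_proba(validation)
    confusion = ConfusionCounts.from_pairs(truth, predicted, model.classes)

    metrics: dict[str, float | None] = {
        "accuracy": float(np.mean(np.array(truth) == np.array(predicted)))
    }
    if model.scheme.is_binary:
        tp, fp, tn, fn = confusion.binary_counts(
            positive=model.scheme.positive_class or ALCOHOL
        )
        metrics = metrics_from_counts(tp, fp, tn, fn)

    roc: dict[str, dict] = {}
    aucs = []
    for ci, cls in enumerate(model.classes):
        y_bin = [t == cls for t in truth]
        if not (any(y_bin) and not all(y_bin)):
            roc[cls] = {"fpr": [], "tpr": [], "auc": None}
            continue
        fpr, tpr, auc = roc_curve(proba[:, ci], y_bin, positive_label=True)
        roc[cls] = {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "auc": auc}
        aucs.append(auc)
    auc_macro = float(np.mean(aucs)) if aucs else None

    row_pct = confusion.row_percent()
    per_class_recall = {
        cls: (None if np.isnan(row_pct[i, i]) else float(row_pct[i, i] / 100.0))
        for i, cls in enumerate(model.classes)
    }
    return EvaluationReport(
        scheme_name=model.scheme.name,
        confusion=confusion,
        metrics=metrics,
        metrics_percent={k: percent(v) for k, v in metrics.items()},
        roc=roc,
        auc_macro=auc_macro,
        per_class_recall=per_class_recall,
        n_evaluated=len(truth),
        provenance=provenance or {},
    )
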