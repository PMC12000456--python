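"""Confusion matrix and the derived accuracy / precision / recall suite.

Per-class one-vs-rest counts come straight from the matrix (rows = true,
columns = predicted): TP_i = counts[i,i], FP_i = column sum - TP_i,
FN_i = row sum - TP_i, TN_i = total - TP_i - FP_i - FN_i. Macro averages are
plain means of the per-class metrics; micro averages pool the one-vs-rest
counts (for single-label classification this makes micro precision, micro
recall and accuracy identical, since every false positive is some class's
false negative). F1 is the harmonic mean of the macro precision and recall.
A zero-denominator precision or recall is defined as 0 and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # C x C, rows = true class, columns = predicted
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        c = len(self.class_names)
        if self.counts.shape != (c, c):
            raise ValueError(f"counts must be {c}x{c}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self) -> dict[str, np.ndarray]:
        tp = np.diag(self.counts).astype(float)
        fp = self.counts.sum(axis=0) - tp
        fn = self.counts.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


@dataclass
class MetricsReport:
    accuracy: float
    error: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    macro_precision: float
    macro_recall: float
    micro_precision: float
    micro_recall: float
    f1: float
    class_names: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "error": self.error,
            "per_class_precision": dict(zip(self.class_names,
                                            map(float, self.per_class_precision))),
            "per_class_recall": dict(zip(self.class_names,
                                         map(float, self.per_class_recall))),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "micro_precision": self.micro_precision,
            "micro_recall": self.micro_recall,
            "f1": self.f1,
        }


def confusion_matrix(truth, predicted, class_names) -> ConfusionMatrix:
    """counts[i, j] = number of samples with true class i predicted as j."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) == 0:
        raise ValueError("empty label sequences")
    if len(truth) != len(predicted):
        raise ValueError(f"length mismatch: {len(truth)} truth vs {len(predicted)} predicted")
    class_names = tuple(class_names)
    index = {c: i for i, c in enumerate(class_names)}
    counts = np.zeros((len(class_names), len(class_names)), dtype=int)
    for t, p in zip(truth, predicted):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, class_names)


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    if (~nz).any():
        log.info("%s undefined (zero denominator) for %d class(es); reported as 0",
                 what, int((~nz).sum()))
    return out


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    ovr = cm.one_vs_rest()
    tp, fp, fn = ovr["tp"], ovr["fp"], ovr["fn"]
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    accuracy = float(tp.sum() / cm.total)
    macro_p = float(precision.mean())
    macro_r = float(recall.mean())
    micro_p = float(tp.sum() / (tp.sum() + fp.sum())) if (tp.sum() + fp.sum()) else 0.0
    micro_r = float(tp.sum() / (tp.sum() + fn.sum())) if (tp.sum() + fn.sum()) else 0.0
    f1 = 2 * macro_p * macro_r / (macro_p + macro_r) if (macro_p + macro_r) else 0.0
    return MetricsReport(
        accuracy=accuracy, error=1.0 - accuracy,
        per_class_precision=precision, per_class_recall=recall,
        macro_precision=macro_p, macro_recall=macro_r,
        micro_precision=micro_p, micro_recall=micro_r,
        f1=float(f1), class_names=cm.class_names)


def evaluate_predictions(truth, predicted, class_names) -> MetricsReport:
    return compute_metrics(confusion_matrix(truth, predicted, class_names))
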