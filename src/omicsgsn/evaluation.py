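"""Classification metrics: confusion counts, recall/precision/accuracy/F1, AUC.

Metrics are computed from one-vs-rest confusion counts:

    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Micro averaging pools the counts across classes before applying the
formulas (for single-label multi-class data micro precision = micro
recall = accuracy); macro averages the per-class metrics.  AUC is the
one-vs-rest ROC area per class via the rank (Mann-Whitney) statistic with
half-credit for ties, macro-averaged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .io_preprocess import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """K x K confusion matrix plus per-class one-vs-rest TP/FP/TN/FN."""

    matrix: np.ndarray  # (K, K), rows = true class, cols = predicted
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return int(self.matrix.sum())


@dataclass
class EvaluationReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    averaging: str
    auc: float | None = None
    per_class: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "averaging": self.averaging,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "per_class": self.per_class,
        }


def confusion_counts(y_true, y_pred, n_classes: int | None = None) -> ConfusionCounts:
    """Exact confusion matrix and one-vs-rest counts."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValidationError("y_true and y_pred lengths differ")
    if yt.size == 0:
        raise ValidationError("empty label sequences")
    k = n_classes if n_classes is not None else int(max(yt.max(), yp.max())) + 1
    if yt.min() < 0 or yp.min() < 0 or yt.max() >= k or yp.max() >= k:
        raise ValidationError("class index out of range")
    matrix = np.zeros((k, k), dtype=int)
    np.add.at(matrix, (yt, yp), 1)
    tp = np.diag(matrix).copy()
    fp = matrix.sum(axis=0) - tp
    fn = matrix.sum(axis=1) - tp
    tn = matrix.sum() - tp - fp - fn
    return ConfusionCounts(matrix=matrix, tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("0/0 in %s; reporting 0", what)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts, averaging: str = "micro") -> EvaluationReport:
    """Recall / precision / accuracy / F1 from confusion counts."""
    if averaging not in ("micro", "macro"):
        raise ValidationError(f"unknown averaging {averaging!r}")
    n = counts.n_samples
    per_class = {}
    precs, recs, f1s = [], [], []
    for c in range(counts.n_classes):
        tp, fp, tn, fn = (int(counts.tp[c]), int(counts.fp[c]),
                          int(counts.tn[c]), int(counts.fn[c]))
        prec = _safe_div(tp, tp + fp, f"precision of class {c}")
        rec = _safe_div(tp, tp + fn, f"recall of class {c}")
        f1 = _safe_div(2 * prec * rec, prec + rec, f"F1 of class {c}")
        per_class[c] = {"tp": tp, "fp": fp, "tn": tn, "fn": fn,
                        "precision": prec, "recall": rec, "f1": f1}
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    accuracy = _safe_div(int(np.trace(counts.matrix)), n, "accuracy")
    if averaging == "micro":
        tp, fp, fn = int(counts.tp.sum()), int(counts.fp.sum()), int(counts.fn.sum())
        precision = _safe_div(tp, tp + fp, "micro precision")
        recall = _safe_div(tp, tp + fn, "micro recall")
        f1 = _safe_div(2 * precision * recall, precision + recall, "micro F1")
    else:
        precision = float(np.mean(precs))
        recall = float(np.mean(recs))
        f1 = float(np.mean(f1s))
    return EvaluationReport(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        averaging=averaging, per_class=per_class,
    )


def binary_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney rank statistic; ties get half credit."""
    yt = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(yt.sum())
    n_neg = yt.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both positive and negative samples")
    ranks = rankdata(s)  # average ranks handle ties with half credit
    u = ranks[yt == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_auc(y_true, probability_rows, averaging: str = "macro_ovr") -> float:
    """Macro one-vs-rest AUC from class-probability rows."""
    if averaging != "macro_ovr":
        raise ValidationError(f"unknown AUC averaging {averaging!r}")
    yt = np.asarray(y_true, dtype=int)
    probs = np.asarray(probability_rows, dtype=float)
    if probs.ndim != 2 or probs.shape[0] != yt.shape[0]:
        raise ValidationError("probability_rows shape does not match y_true")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("probability rows must sum to 1")
    aucs = []
    for c in range(probs.shape[1]):
        pos = (yt == c).astype(int)
        if pos.sum() == 0:
            logger.warning("class %d absent from y_true; skipped in AUC", c)
            continue
        if pos.sum() == pos.size:
            logger.warning("only class %d present in y_true; skipped in AUC", c)
            continue
        aucs.append(binary_auc(pos, probs[:, c]))
    if not aucs:
        raise ValidationError("no class had both positives and negatives")
    return float(np.mean(aucs))


def evaluate_predictions(
    y_true, probability_rows, class_names: list[str] | None = None
) -> dict:
    """Full report: micro and macro Eqs-of-counts metrics plus macro OvR AUC."""
    probs = np.asarray(probability_rows, dtype=float)
    yt = np.asarray(y_true, dtype=int)
    yp = probs.argmax(axis=1)
    counts = confusion_counts(yt, yp, n_classes=probs.shape[1])
    auc = compute_auc(yt, probs)
    micro = compute_metrics(counts, "micro")
    macro = compute_metrics(counts, "macro")
    micro.auc = macro.auc = auc
    return {
        "n_samples": int(yt.size),
        "class_names": class_names,
        "confusion_matrix": counts.matrix.tolist(),
        "micro": micro.to_dict(),
        "macro": macro.to_dict(),
        "auc_macro_ovr": auc,
    }


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
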