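"""Stratified splitting, confusion matrices, macro metrics, and McNemar's test."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion matrix (rows = true, cols = predicted) with macro metrics."""

    confusion_matrix: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class: dict[int, dict[str, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.confusion_matrix.tolist(),
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": {str(k): v for k, v in self.per_class.items()},
        }


@dataclass(frozen=True)
class McNemarResult:
    """Discordant-pair counts and the paired chi-square statistic."""

    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    chi_square: float
    p_value: float
    correction: bool


def stratified_split(
    labels: np.ndarray,
    train_frac: float = 0.85,
    val_frac_of_train: float = 0.20,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class random split into (train, val, test) index arrays.

    Class proportions are preserved within ±1 sample; validation is carved
    from the training share. Deterministic for a fixed seed.
    """
    labels = np.asarray(labels)
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must lie in (0, 1)")
    if not (0 <= val_frac_of_train < 1):
        raise ValueError("val_frac_of_train must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, val_idx, test_idx = [], [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < 3:
            raise ValueError(f"class {c!r} has fewer than 3 samples")
        idx = rng.permutation(idx)
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        n_val = int(round(val_frac_of_train * n_train))
        test_idx.append(idx[n_train:])
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:n_train])
    return (
        np.sort(np.concatenate(train_idx)),
        np.sort(np.concatenate(val_idx)),
        np.sort(np.concatenate(test_idx)),
    )


def confusion(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """Count matrix with counts[t, p] = #(true = t and predicted = p)."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size and (
        min(y_true.min(), y_pred.min()) < 0 or max(y_true.max(), y_pred.max()) >= n_classes
    ):
        raise ValueError("label out of range")
    mat = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(mat, (y_true, y_pred), 1)
    return mat


def macro_report(matrix: np.ndarray) -> ClassificationReport:
    """Macro-averaged precision/recall/F1 and overall accuracy from a matrix.

    Accuracy is trace/total. Per-class precision = TP/(TP+FP) and recall =
    TP/(TP+FN); a class with zero predicted (or zero true) instances
    contributes 0 to the affected metric, with a warning.
    """
    mat = np.asarray(matrix, dtype=np.int64)
    total = int(mat.sum())
    if total == 0:
        raise ValueError("all-zero confusion matrix")
    n = mat.shape[0]
    precisions, recalls, f1s = [], [], []
    per_class: dict[int, dict[str, int]] = {}
    for c in range(n):
        tp = int(mat[c, c])
        fp = int(mat[:, c].sum() - tp)
        fn = int(mat[c, :].sum() - tp)
        tn = total - tp - fp - fn
        per_class[c] = {"TP": tp, "FP": fp, "FN": fn, "TN": tn}
        if tp + fp == 0:
            logger.warning("class %d has no predicted instances; precision set to 0", c)
            prec = 0.0
        else:
            prec = tp / (tp + fp)
        if tp + fn == 0:
            logger.warning("class %d has no true instances; recall set to 0", c)
            rec = 0.0
        else:
            rec = tp / (tp + fn)
        f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
    return ClassificationReport(
        confusion_matrix=mat,
        accuracy=float(np.trace(mat)) / total,
        macro_precision=float(np.mean(precisions)),
        macro_recall=float(np.mean(recalls)),
        macro_f1=float(np.mean(f1s)),
        per_class=per_class,
    )


def mcnemar(y_true: np.ndarray, pred_a: np.ndarray, pred_b: np.ndarray,
            correction: bool = True) -> McNemarResult:
    """McNemar's paired test on the correctness discordance of two classifiers.

    χ² = (|b−c|−1)²/(b+c) with the continuity correction, (b−c)²/(b+c)
    without; p from the χ² distribution with 1 degree of freedom. With no
    discordant pairs the statistic is 0 and p = 1.
    """
    y_true = np.asarray(y_true)
    pred_a = np.asarray(pred_a)
    pred_b = np.asarray(pred_b)
    if not (y_true.shape == pred_a.shape == pred_b.shape):
        raise ValueError("all inputs must have equal length")
    a_ok = pred_a == y_true
    b_ok = pred_b == y_true
    b_count = int(np.sum(a_ok & ~b_ok))
    c_count = int(np.sum(~a_ok & b_ok))
    denom = b_count + c_count
    if denom == 0:
        return McNemarResult(b=b_count, c=c_count, chi_square=0.0, p_value=1.0,
                             correction=correction)
    diff = abs(b_count - c_count)
    if correction:
        diff = max(diff - 1, 0)
    chi2 = diff**2 / denom
    p = float(stats.chi2.sf(chi2, df=1))
    return McNemarResult(b=b_count, c=c_count, chi_square=float(chi2), p_value=p,
                         correction=correction)
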