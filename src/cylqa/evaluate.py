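"""Classification metrics, ROC/AUC, GPR distributions and the CNN-vs-GPR tables."""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .gamma import CLINICAL_CRITERIA, GammaCriteria, gamma_analysis, gpr_classify
from .simulate import PlanSample

__all__ = [
    "confusion_matrix",
    "metrics_from_confusion",
    "roc_auc",
    "gpr_distributions",
    "binary_compare",
    "EvalReport",
    "build_report",
]

CLASS_NAMES = ("normal", "gantry", "collimator", "couch", "dose")


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int = 5) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _binary_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    total = tp + fp + fn + tn
    accuracy = (tp + tn) / total
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision defined as 0",
                      stacklevel=3)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = 0.0 if tp + fn == 0 else tp / (tp + fn)
    f1 = (0.0 if precision + recall == 0
          else 2.0 * precision * recall / (precision + recall))
    return {"accuracy": accuracy, "precision": precision,
            "recall": recall, "f1": f1}


def metrics_from_confusion(cm: np.ndarray) -> dict[str, float]:
    """Accuracy/precision/recall/F1 from a confusion matrix.

    A 2x2 matrix (rows/cols ordered negative, positive) is scored with the
    binary formulas directly; larger matrices are scored one-vs-rest per
    class and macro-averaged.  Cells with no predicted positives contribute 0
    with a warning.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.sum() == 0:
        raise ValueError("confusion matrix must be square and non-empty")
    if cm.shape == (2, 2):
        tn, fp = int(cm[0, 0]), int(cm[0, 1])
        fn, tp = int(cm[1, 0]), int(cm[1, 1])
        return _binary_metrics(tp, fp, fn, tn)
    n = cm.shape[0]
    total = int(cm.sum())
    per_class = []
    for k in range(n):
        tp = int(cm[k, k])
        fp = int(cm[:, k].sum()) - tp
        fn = int(cm[k, :].sum()) - tp
        tn = total - tp - fp - fn
        per_class.append(_binary_metrics(tp, fp, fn, tn))
    return {
        "accuracy": float(np.trace(cm)) / total,
        "precision": float(np.mean([m["precision"] for m in per_class])),
        "recall": float(np.mean([m["recall"] for m in per_class])),
        "f1": float(np.mean([m["f1"] for m in per_class])),
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray, positive_class: int
            ) -> tuple[float, np.ndarray, np.ndarray]:
    """One-vs-rest ROC from per-class probabilities.

    ``scores`` is (n, n_classes) (or a 1-D score vector used directly);
    returns (AUC by the trapezoidal rule, fpr, tpr).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    s = scores if scores.ndim == 1 else scores[:, positive_class]
    y = (labels == positive_class).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, _ = _roc_curve(y, s)
    return float(_trapezoid_auc(fpr, tpr)), fpr, tpr


def _five_number(values: np.ndarray) -> dict[str, float]:
    q = np.percentile(values, [0, 25, 50, 75, 100])
    return {"min": float(q[0]), "q1": float(q[1]), "median": float(q[2]),
            "q3": float(q[3]), "max": float(q[4])}


def gpr_distributions(samples: Sequence[PlanSample],
                      criteria_list: Sequence[GammaCriteria] = CLINICAL_CRITERIA,
                      results: Mapping[str, Sequence[object]] | None = None,
                      **gamma_kw) -> dict[str, dict[str, dict]]:
    """Per-class, per-criterion five-number summaries of the pass rates.

    ``results`` may carry precomputed per-sample GammaResults (keyed by
    criterion label, aligned with ``samples``) to avoid re-running gamma.
    """
    classes = np.array([int(s.label.error_class) for s in samples])
    out: dict[str, dict[str, dict]] = {}
    for cls in sorted(set(classes.tolist())):
        member_idx = np.nonzero(classes == cls)[0]
        row: dict[str, dict] = {}
        for crit in criteria_list:
            if results is not None:
                gprs = np.array([results[crit.label][i].gpr for i in member_idx])
            else:
                gprs = np.array([
                    gamma_analysis(samples[i].measured, samples[i].calculated,
                                   crit, **gamma_kw).gpr
                    for i in member_idx])
            row[crit.label] = {**_five_number(gprs), "values": gprs.tolist()}
        out[CLASS_NAMES[cls]] = row
    return out


def _rows_to_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["pairing", "method", "accuracy",
                                       "precision", "recall", "f1"])


def binary_compare(pred_labels: np.ndarray, samples: Sequence[PlanSample],
                   gpr_results: Mapping[str, Sequence[object]],
                   criteria_list: Sequence[GammaCriteria] = CLINICAL_CRITERIA,
                   ) -> pd.DataFrame:
    """Binary-collapse comparison of the CNN against GPR thresholding.

    CNN rows ("X vs others") score predicted-class == X against the full test
    set.  GPR rows for an error class X ("X vs normal") restrict to the
    normal + X subset, call a plan an error when its pass rate fails the
    bound, and take X as the positive class.  The GPR "normal vs others" row
    uses the full set with normal positive and pass meaning normal.
    ``gpr_results`` maps each criterion label to per-sample GammaResults
    aligned with ``samples``.
    """
    y_true = np.array([int(s.label.error_class) for s in samples])
    pred_labels = np.asarray(pred_labels, dtype=int)
    if len(pred_labels) != len(samples):
        raise ValueError("predictions and samples are misaligned")
    rows: list[dict] = []
    for cls in range(5):
        name = CLASS_NAMES[cls]
        cm = confusion_matrix((y_true == cls).astype(int),
                              (pred_labels == cls).astype(int), n_classes=2)
        rows.append({"pairing": f"{name} vs others", "method": "CNN",
                     **metrics_from_confusion(cm)})
        for crit in criteria_list:
            results = gpr_results[crit.label]
            passed = np.array([gpr_classify(r) for r in results])
            if cls == 0:
                mask = np.ones(len(samples), dtype=bool)
                true_pos = y_true == 0
                pred_pos = passed  # predicted normal iff pass
                pairing = "normal vs others"
            else:
                mask = (y_true == 0) | (y_true == cls)
                if not mask.any():
                    raise ValueError(f"empty pairing subset for class {name}")
                true_pos = y_true == cls
                pred_pos = ~passed  # predicted error iff fail
                pairing = f"{name} vs normal"
            cm = confusion_matrix(true_pos[mask].astype(int),
                                  pred_pos[mask].astype(int), n_classes=2)
            rows.append({"pairing": pairing, "method": crit.label,
                         **metrics_from_confusion(cm)})
    return _rows_to_frame(rows)


@dataclasses.dataclass
class EvalReport:
    """Everything the comparison emits, JSON-serializable."""

    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class_auc: dict[str, float]
    normal_vs_error_auc: float
    confusion: np.ndarray
    gpr_summaries: dict
    binary_table: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class_auc": self.per_class_auc,
            "normal_vs_error_auc": self.normal_vs_error_auc,
            "confusion": self.confusion.tolist(),
            "gpr_summaries": {
                cls: {crit: {k: v for k, v in d.items() if k != "values"}
                      for crit, d in row.items()}
                for cls, row in self.gpr_summaries.items()},
            "binary_table": self.binary_table.to_dict(orient="records"),
        }


def build_report(probs: np.ndarray, samples: Sequence[PlanSample],
                 criteria_list: Sequence[GammaCriteria] = CLINICAL_CRITERIA,
                 **gamma_kw) -> EvalReport:
    """Run the full evaluation of ensemble predictions against GPR thresholds."""
    probs = np.asarray(probs, dtype=float)
    y_true = np.array([int(s.label.error_class) for s in samples])
    y_pred = probs.argmax(axis=1)
    cm = confusion_matrix(y_true, y_pred)
    metrics = metrics_from_confusion(cm)
    per_class_auc = {}
    for cls in range(5):
        if (y_true == cls).any() and (y_true != cls).any():
            per_class_auc[CLASS_NAMES[cls]] = roc_auc(probs, y_true, cls)[0]
    # normal-vs-error: normal probability scores normal (class 0) positive
    normal_auc = per_class_auc.get("normal", float("nan"))
    gpr_results = {
        crit.label: [gamma_analysis(s.measured, s.calculated, crit, **gamma_kw)
                     for s in samples]
        for crit in criteria_list}
    table = binary_compare(y_pred, samples, gpr_results, criteria_list)
    summaries = gpr_distributions(samples, criteria_list, results=gpr_results)
    return EvalReport(
        accuracy=metrics["accuracy"], macro_precision=metrics["precision"],
        macro_recall=metrics["recall"], macro_f1=metrics["f1"],
        per_class_auc=per_class_auc, normal_vs_error_auc=normal_auc,
        confusion=cm, gpr_summaries=summaries, binary_table=table)
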