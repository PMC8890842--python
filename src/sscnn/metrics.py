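"""Multiclass evaluation: confusion matrix, per-class / micro / macro
precision-recall-F1, and one-vs-rest ROC AUC.

Conventions:
* multiclass accuracy is trace/total of the confusion matrix (the
  TP+TN over N form of the binary definition reduces to this at 2 classes);
* micro averages pool TP/FP/FN over classes (for single-label data,
  micro precision = micro recall = micro F1 = accuracy);
* macro averages are unweighted means of per-class values;
* any 0/0 metric is reported as 0.0 with a warning;
* AUC uses the midrank (Mann-Whitney) convention for tied scores;
  a class absent from the truth gets a NaN per-class AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


# --------------------------------------------------------------------
# counting
# --------------------------------------------------------------------
def confusion_matrix(true_labels, predicted_labels, n_classes: int) -> np.ndarray:
    """n_classes x n_classes counts; rows = true class, cols = predicted."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label sequences must have equal length")
    for name, arr in (("true", t), ("predicted", p)):
        if len(arr) and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} labels outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


def per_class_counts(cm: np.ndarray, class_c: int) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) for one class of a confusion matrix."""
    cm = np.asarray(cm)
    if not 0 <= class_c < cm.shape[0]:
        raise ValueError(f"class {class_c} outside [0, {cm.shape[0]})")
    tp = int(cm[class_c, class_c])
    fp = int(cm[:, class_c].sum()) - tp
    fn = int(cm[class_c, :].sum()) - tp
    tn = int(cm.sum()) - tp - fp - fn
    return tp, fp, fn, tn


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: 0/0 reported as 0.0", RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


# --------------------------------------------------------------------
# metrics from a confusion matrix
# --------------------------------------------------------------------
def basic_metrics(cm: np.ndarray) -> dict:
    """Accuracy plus per-class precision/recall/F1 arrays."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    noc = cm.shape[0]
    precision = np.zeros(noc)
    recall = np.zeros(noc)
    f1 = np.zeros(noc)
    for c in range(noc):
        tp, fp, fn, _ = per_class_counts(cm, c)
        precision[c] = _safe_div(tp, tp + fp, f"precision class {c}")
        recall[c] = _safe_div(tp, tp + fn, f"recall class {c}")
        f1[c] = _safe_div(2 * precision[c] * recall[c], precision[c] + recall[c], f"F1 class {c}")
    return {
        "accuracy": np.trace(cm) / total,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def micro_metrics(cm: np.ndarray) -> dict:
    """Micro-averaged precision/recall/F1 (pooled per-class counts)."""
    cm = np.asarray(cm)
    if cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    tps, fps, fns = 0, 0, 0
    for c in range(cm.shape[0]):
        tp, fp, fn, _ = per_class_counts(cm, c)
        tps, fps, fns = tps + tp, fps + fp, fns + fn
    precision = _safe_div(tps, tps + fps, "micro precision")
    recall = _safe_div(tps, tps + fns, "micro recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "micro F1")
    return {"precision": precision, "recall": recall, "f1": f1}


def macro_metrics(cm: np.ndarray) -> dict:
    """Macro-averaged precision/recall/F1 (unweighted class means)."""
    basic = basic_metrics(cm)
    return {
        "precision": float(np.mean(basic["precision"])),
        "recall": float(np.mean(basic["recall"])),
        "f1": float(np.mean(basic["f1"])),
    }


# --------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------
def _binary_auc(y: np.ndarray, score: np.ndarray) -> float:
    """One-vs-rest AUC via the midrank Mann-Whitney statistic."""
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = rankdata(score)  # midranks for ties
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def roc_auc(true_labels, probs: np.ndarray) -> dict:
    """Per-class one-vs-rest AUC, plus micro and macro aggregates.

    micro flattens the one-hot indicators against all class scores;
    macro is the unweighted mean over classes present in the truth.
    """
    t = np.asarray(true_labels, dtype=np.int64)
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2 or probs.shape[0] != len(t):
        raise ValueError("probs must be (n_samples, n_classes) aligned with labels")
    _check_row_stochastic(probs)
    noc = probs.shape[1]
    onehot = np.eye(noc)[t]
    per_class = np.array([_binary_auc(onehot[:, c], probs[:, c]) for c in range(noc)])
    if np.isnan(per_class).any():
        missing = [c for c in range(noc) if np.isnan(per_class[c])]
        warnings.warn(f"classes absent from truth, per-class AUC undefined: {missing}", RuntimeWarning)
    micro = _binary_auc(onehot.ravel(), probs.ravel())
    macro = float(np.nanmean(per_class))
    return {"per_class": per_class, "micro": micro, "macro": macro}


def _check_row_stochastic(probs: np.ndarray, tol: float = 1e-5) -> None:
    if (probs < -tol).any() or np.abs(probs.sum(axis=1) - 1.0).max() > tol:
        raise ValueError("probability rows must be non-negative and sum to 1")


# --------------------------------------------------------------------
# full report
# --------------------------------------------------------------------
@dataclass
class MetricsReport:
    """Every headline quantity of a multiclass evaluation."""

    confusion: np.ndarray
    accuracy: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    per_class_f1: np.ndarray
    micro_precision: float
    micro_recall: float
    micro_f1: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class_auc: np.ndarray
    micro_auc: float
    macro_auc: float
    class_names: list[str]

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        """One-column summary table (percent scale by default)."""
        scale = 100.0 if percent else 1.0
        rows = {
            "Accuracy": self.accuracy,
            "Micro-precision": self.micro_precision,
            "Micro-recall": self.micro_recall,
            "Micro-F1-score": self.micro_f1,
            "Micro-AUC": self.micro_auc,
            "Macro-precision": self.macro_precision,
            "Macro-recall": self.macro_recall,
            "Macro-F1-score": self.macro_f1,
            "Macro-AUC": self.macro_auc,
        }
        return pd.DataFrame(
            {"value": [round(v * scale, 2) for v in rows.values()]}, index=list(rows)
        )

    def per_class_frame(self, percent: bool = True) -> pd.DataFrame:
        scale = 100.0 if percent else 1.0
        return pd.DataFrame(
            {
                "precision": np.round(self.per_class_precision * scale, 2),
                "recall": np.round(self.per_class_recall * scale, 2),
                "f1": np.round(self.per_class_f1 * scale, 2),
                "auc": np.round(self.per_class_auc * scale, 2),
            },
            index=self.class_names,
        )


def report_from_predictions(
    true_labels, probs: np.ndarray, class_names: list[str]
) -> MetricsReport:
    """Build the full report from labels and a probability matrix."""
    t = np.asarray(true_labels, dtype=np.int64)
    pred = np.asarray(probs).argmax(axis=1)
    noc = len(class_names)
    cm = confusion_matrix(t, pred, noc)
    basic = basic_metrics(cm)
    micro = micro_metrics(cm)
    macro = macro_metrics(cm)
    auc = roc_auc(t, probs)
    return MetricsReport(
        confusion=cm,
        accuracy=float(basic["accuracy"]),
        per_class_precision=basic["precision"],
        per_class_recall=basic["recall"],
        per_class_f1=basic["f1"],
        micro_precision=micro["precision"],
        micro_recall=micro["recall"],
        micro_f1=micro["f1"],
        macro_precision=macro["precision"],
        macro_recall=macro["recall"],
        macro_f1=macro["f1"],
        per_class_auc=auc["per_class"],
        micro_auc=auc["micro"],
        macro_auc=auc["macro"],
        class_names=list(class_names),
    )


def evaluation_report(model, eval_set) -> MetricsReport:
    """Evaluate a fitted classifier on a LabeledImageSet."""
    if len(eval_set) == 0:
        raise ValueError("evaluation set is empty")
    probs = model.predict_proba(eval_set.to_tensors())
    return report_from_predictions(eval_set.labels, probs, eval_set.class_names)


# --------------------------------------------------------------------
# figures (reporting plumbing)
# --------------------------------------------------------------------
def plot_confusion_matrix(cm: np.ndarray, class_names: list[str], path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(cm, cmap="Blues")
    ax.set_xticks(range(len(class_names)), class_names, rotation=45)
    ax.set_yticks(range(len(class_names)), class_names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(j, i, str(cm[i, j]), ha="center", va="center")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc_curves(true_labels, probs: np.ndarray, class_names: list[str], path) -> None:
    """One-vs-rest ROC curve per class with its AUC in the legend."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    t = np.asarray(true_labels)
    aucs = roc_auc(t, probs)["per_class"]
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for c, name in enumerate(class_names):
        fpr, tpr, _ = roc_curve((t == c).astype(int), probs[:, c])
        ax.plot(fpr, tpr, label=f"{name} (AUC {aucs[c]:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
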