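"""Multiclass performance metrics with one-vs-rest ROC analysis.

For a multiclass probabilistic classifier, each class ``i`` is evaluated as
a binary problem (class ``i`` vs the rest) using the predicted probability
of that class as the score, yielding classwise AUROC values.  These are
aggregated two ways:

* **micro-average** — every instance weighted equally: the binarized
  (instance, class) pairs of all classes are pooled into one binary problem
  and a single ROC computed on the pool;
* **macro-average** — every class weighted equally: the arithmetic mean of
  the classwise AUROCs.

Micro is dominated by large classes; macro treats rare families on equal
footing with abundant ones, which matters for heavily skewed family sizes.
Standard metrics (accuracy, macro precision / recall / F-score) accompany
the ROC analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    auc,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_curve,
)
from sklearn.preprocessing import label_binarize

__all__ = [
    "ROCCurve",
    "EvaluationReport",
    "binary_roc",
    "multiclass_auroc",
    "classification_metrics",
    "evaluate_classifier",
    "render_report",
]


@dataclass
class ROCCurve:
    """A ROC curve and its trapezoidal area.

    The curve runs from (0, 0) to (1, 1); ties in scores are handled by the
    threshold sweep, so the trapezoidal area equals the Mann-Whitney
    probability that a random positive outscores a random negative with tied
    pairs counting one half.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float


def binary_roc(scores: Sequence[float], truth: Sequence[int]) -> ROCCurve:
    """ROC curve of real-valued scores against binary truth."""
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(truth)
    if classes.size != 2:
        raise ValueError(
            f"AUROC undefined: truth contains {classes.size} class(es), need 2"
        )
    fpr, tpr, _ = roc_curve(truth, scores)
    return ROCCurve(fpr=fpr, tpr=tpr, auroc=float(auc(fpr, tpr)))


def multiclass_auroc(
    probas: np.ndarray,
    truth: Sequence[str],
    class_names: Sequence[str],
) -> tuple[float, float, dict[str, float]]:
    """One-vs-rest micro / macro AUROC and the classwise values.

    ``probas`` rows are per-class probability vectors in ``class_names``
    order.  A class absent from the truth has undefined one-vs-rest AUROC
    and is excluded from the macro average with a warning.  The micro AUROC
    pools the binarized instance set of all classes into one binary ROC.
    """
    probas = np.asarray(probas, dtype=float)
    truth = np.asarray(truth)
    if probas.shape[1] != len(class_names):
        raise ValueError("probability width does not match the class manifest")
    if len(class_names) < 2:
        raise ValueError("need at least 2 classes")
    onehot = label_binarize(truth, classes=list(class_names))
    if len(class_names) == 2 and onehot.shape[1] == 1:
        onehot = np.hstack([1 - onehot, onehot])
    classwise: dict[str, float] = {}
    for i, name in enumerate(class_names):
        col = onehot[:, i]
        if col.min() == col.max():
            warnings.warn(
                f"class {name!r} absent from truth; excluded from macro AUROC",
                stacklevel=2,
            )
            continue
        classwise[name] = binary_roc(probas[:, i], col).auroc
    if not classwise:
        raise ValueError("no class present in truth")
    macro = float(np.mean(list(classwise.values())))
    micro = binary_roc(probas.ravel(), onehot.ravel()).auroc
    return micro, macro, classwise


@dataclass
class EvaluationReport:
    """Complete held-out evaluation of one classifier."""

    class_names: list[str]
    accuracy: float
    precision_per_class: dict[str, float]
    recall_per_class: dict[str, float]
    f_per_class: dict[str, float]
    macro_precision: float
    macro_recall: float
    macro_f: float
    classwise_auroc: dict[str, float] = field(default_factory=dict)
    micro_auroc: float | None = None
    macro_auroc: float | None = None
    confusion: np.ndarray | None = None
    roc_curves: dict[str, ROCCurve] = field(default_factory=dict)

    def summary_row(self) -> dict[str, float | None]:
        return {
            "Accuracy": self.accuracy,
            "Precision": self.macro_precision,
            "Recall": self.macro_recall,
            "F-score": self.macro_f,
            "Micro AUROC": self.micro_auroc,
            "Macro AUROC": self.macro_auroc,
        }


def classification_metrics(
    predicted: Sequence[str], truth: Sequence[str], class_names: Sequence[str]
) -> EvaluationReport:
    """Accuracy plus per-class and macro precision / recall / F-score.

    The F-score per class is the harmonic mean of that class's precision and
    recall; macro values are unweighted means over classes present in the
    truth.  A class with zero predicted positives gets precision 0 (flagged
    with a warning by the underlying metric routine being overridden here to
    stay silent-but-zero).
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape[0]} predictions vs "
            f"{truth.shape[0]} truth labels"
        )
    labels = list(class_names)
    prec, rec, f1, _ = precision_recall_fscore_support(
        truth, predicted, labels=labels, zero_division=0
    )
    present = [i for i, name in enumerate(labels) if np.any(truth == name)]
    conf = confusion_matrix(truth, predicted, labels=labels)
    return EvaluationReport(
        class_names=labels,
        accuracy=float(np.mean(predicted == truth)),
        precision_per_class={labels[i]: float(prec[i]) for i in range(len(labels))},
        recall_per_class={labels[i]: float(rec[i]) for i in range(len(labels))},
        f_per_class={labels[i]: float(f1[i]) for i in range(len(labels))},
        macro_precision=float(np.mean(prec[present])),
        macro_recall=float(np.mean(rec[present])),
        macro_f=float(np.mean(f1[present])),
        confusion=conf,
    )


def evaluate_classifier(
    probas: np.ndarray,
    truth: Sequence[str],
    class_names: Sequence[str],
) -> EvaluationReport:
    """Full report (standard metrics + ROC analysis) from probability rows."""
    probas = np.asarray(probas, dtype=float)
    predicted = np.asarray(class_names)[probas.argmax(axis=1)]
    report = classification_metrics(predicted, truth, class_names)
    micro, macro, classwise = multiclass_auroc(probas, truth, class_names)
    report.micro_auroc = micro
    report.macro_auroc = macro
    report.classwise_auroc = classwise
    onehot = label_binarize(np.asarray(truth), classes=list(class_names))
    if len(class_names) == 2 and onehot.shape[1] == 1:
        onehot = np.hstack([1 - onehot, onehot])
    for i, name in enumerate(class_names):
        if name in classwise:
            report.roc_curves[name] = binary_roc(probas[:, i], onehot[:, i])
    report.roc_curves["micro"] = binary_roc(probas.ravel(), onehot.ravel())
    return report


def render_report(
    reports: dict[str, EvaluationReport], out_dir: str | Path
) -> pd.DataFrame:
    """Write the metric table (CSV) and one ROC figure per model.

    The CSV has one row per model with the six summary columns (Accuracy,
    Precision, Recall, F-score, Micro AUROC, Macro AUROC).  Each ROC figure
    shows the classwise curves in gray with the micro-average overlaid.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(
        {name: rep.summary_row() for name, rep in reports.items()}
    ).T
    table.index.name = "Model"
    table.to_csv(out_dir / "metrics.csv")
    for name, rep in reports.items():
        fig, ax = plt.subplots(figsize=(5, 5))
        for cname, curve in rep.roc_curves.items():
            if cname == "micro":
                continue
            ax.plot(curve.fpr, curve.tpr, color="gray", lw=0.6, alpha=0.7)
        if "micro" in rep.roc_curves:
            mc = rep.roc_curves["micro"]
            ax.plot(
                mc.fpr,
                mc.tpr,
                color="crimson",
                lw=1.8,
                label=f"micro (AUROC={mc.auroc:.3f})",
            )
        if rep.macro_auroc is not None:
            ax.plot([], [], " ", label=f"macro AUROC={rep.macro_auroc:.3f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.set_title(f"One-vs-rest ROC: {name}")
        ax.legend(loc="lower right", fontsize=8)
        fig.tight_layout()
        fig.savefig(out_dir / f"roc_{name}.png", dpi=120)
        plt.close(fig)
    return table
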