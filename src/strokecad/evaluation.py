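"""Confusion matrices and one-vs-rest multiclass metrics.

Each class c is scored as a binary problem (c vs rest) from the K x K
confusion matrix (rows = true class, columns = predicted class):

    TP = cm[c][c]          FN = row_c - TP
    FP = col_c - TP        TN = total - TP - FN - FP

    sensitivity = TP/(TP+FN)        specificity = TN/(TN+FP)
    accuracy    = (TP+TN)/total     precision   = TP/(TP+FP)
    F-score     = 2TP/(2TP+FP+FN)
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

All metrics are reported on a x100 percent scale (MCC in [-100, 100]);
0/0 cells return 0 with a warning.  The macro row is the unweighted
arithmetic mean of the per-class values, which is how the per-class
"accuracy" column must be read — the plain multiclass accuracy
(trace/total) is reported separately as ``overall_accuracy``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .errors import InputError

METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "precision", "f_score", "mcc")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise InputError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise InputError("confusion counts must be nonnegative")
        if not self.class_names:
            self.class_names = [f"Class {i}" for i in range(self.counts.shape[0])]

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f_score: float
    mcc: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, m) for m in METRIC_NAMES)


@dataclass
class MetricsReport:
    per_class: list[ClassMetrics]
    macro: ClassMetrics
    overall_accuracy: float
    class_names: list[str]
    epoch_tag: str | None = None


def confusion(true_labels: Sequence[int], predicted_labels: Sequence[int], n_classes: int) -> ConfusionMatrix:
    """Tally counts[t][p] = number of instances with true t, predicted p."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise InputError("true and predicted labels must have equal length")
    for name, arr in (("true", t), ("predicted", p)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise InputError(f"{name} labels outside 0..{n_classes - 1}")
    counts = _sk_confusion(t, p, labels=np.arange(n_classes))
    return ConfusionMatrix(counts=counts)


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        if num != 0:
            raise InputError(f"impossible counts in {what}")
        warnings.warn(f"0/0 in {what}; returning 0 by convention", RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def one_vs_rest_metrics(cm: ConfusionMatrix, c: int) -> ClassMetrics:
    """Binary metrics for class ``c`` against the rest, on a x100 scale."""
    counts = cm.counts
    if cm.total == 0:
        raise InputError("empty confusion matrix")
    tp = float(counts[c, c])
    fn = float(counts[c, :].sum() - tp)
    fp = float(counts[:, c].sum() - tp)
    tn = float(cm.total - tp - fn - fp)
    sens = 100.0 * _ratio(tp, tp + fn, f"sensitivity of class {c}")
    spec = 100.0 * _ratio(tn, tn + fp, f"specificity of class {c}")
    acc = 100.0 * (tp + tn) / cm.total
    prec = 100.0 * _ratio(tp, tp + fp, f"precision of class {c}")
    f1 = 100.0 * _ratio(2.0 * tp, 2.0 * tp + fp + fn, f"F-score of class {c}")
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        warnings.warn(f"0/0 in MCC of class {c}; returning 0 by convention",
                      RuntimeWarning, stacklevel=2)
        mcc = 0.0
    else:
        mcc = 100.0 * (tp * tn - fp * fn) / denom
    return ClassMetrics(sens, spec, acc, prec, f1, mcc)


def macro_average(per_class: Sequence[ClassMetrics]) -> ClassMetrics:
    """Unweighted arithmetic mean of each metric over classes."""
    if not per_class:
        raise InputError("macro_average requires at least one class")
    values = np.array([m.as_tuple() for m in per_class])
    return ClassMetrics(*values.mean(axis=0))


def evaluate_confusion(cm: ConfusionMatrix, epoch_tag: str | None = None) -> MetricsReport:
    per_class = [one_vs_rest_metrics(cm, c) for c in range(cm.n_classes)]
    overall = 100.0 * float(np.trace(cm.counts)) / cm.total
    return MetricsReport(
        per_class=per_class,
        macro=macro_average(per_class),
        overall_accuracy=overall,
        class_names=list(cm.class_names),
        epoch_tag=epoch_tag,
    )


def report_frame(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Per-class blocks with an Average row per epoch tag (2-decimal
    rounding applied here, at serialization, never internally)."""
    rows = []
    for rep in reports:
        tag = rep.epoch_tag or ""
        for name, m in zip(rep.class_names, rep.per_class):
            rows.append({"epoch": tag, "class": name, **dict(zip(METRIC_NAMES, m.as_tuple()))})
        rows.append({"epoch": tag, "class": "Average", **dict(zip(METRIC_NAMES, rep.macro.as_tuple()))})
    df = pd.DataFrame(rows)
    df[list(METRIC_NAMES)] = df[list(METRIC_NAMES)].round(2)
    return df


def summary_frame(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Cross-epoch summary: one macro row per epoch plus their mean."""
    rows = [
        {"epoch": rep.epoch_tag or "", **dict(zip(METRIC_NAMES, rep.macro.as_tuple()))}
        for rep in reports
    ]
    mean = np.array([[r[m] for m in METRIC_NAMES] for r in rows]).mean(axis=0)
    rows.append({"epoch": "Average", **dict(zip(METRIC_NAMES, mean))})
    df = pd.DataFrame(rows)
    df[list(METRIC_NAMES)] = df[list(METRIC_NAMES)].round(2)
    return df


def report_to_json(reports: Sequence[MetricsReport], path: str | Path | None = None) -> str:
    payload = []
    for rep in reports:
        payload.append(
            {
                "epoch_tag": rep.epoch_tag,
                "class_names": rep.class_names,
                "per_class": [asdict(m) for m in rep.per_class],
                "macro": asdict(rep.macro),
                "overall_accuracy": rep.overall_accuracy,
            }
        )
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def report_from_json(source: str | Path) -> list[MetricsReport]:
    text = str(source)
    if not text.lstrip().startswith("["):
        text = Path(source).read_text()
    out = []
    for item in json.loads(text):
        out.append(
            MetricsReport(
                per_class=[ClassMetrics(**m) for m in item["per_class"]],
                macro=ClassMetrics(**item["macro"]),
                overall_accuracy=item["overall_accuracy"],
                class_names=item["class_names"],
                epoch_tag=item["epoch_tag"],
            )
        )
    return out


def diagonal_confusion(diagonal: Sequence[int], class_sizes: Sequence[int],
                       spill_class: int | None = None) -> ConfusionMatrix:
    """Confusion matrix from per-class correct counts and true class sizes.

    Published confusion figures are often only quoted through their
    diagonals; row sums must still equal the class sizes, so the
    unattributed misclassifications of each row are placed in a single
    off-diagonal column (default: the largest class, excluding the row's
    own).  Row-sum-dependent metrics (sensitivity, overall accuracy) are
    exact under any such placement; column-dependent ones are not.
    """
    diag = np.asarray(diagonal, dtype=int)
    sizes = np.asarray(class_sizes, dtype=int)
    if diag.shape != sizes.shape:
        raise InputError("diagonal and class_sizes must have equal length")
    if (diag > sizes).any() or (diag < 0).any():
        raise InputError("diagonal counts must lie in [0, class size]")
    k = diag.size
    counts = np.diag(diag)
    default_spill = int(np.argmax(sizes))
    for c in range(k):
        rest = sizes[c] - diag[c]
        if rest > 0:
            col = spill_class if spill_class is not None else default_spill
            if col == c:
                col = (c + 1) % k
            counts[c, col] += rest
    return ConfusionMatrix(counts=counts)
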