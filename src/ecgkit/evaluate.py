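"""Confusion matrices and the per-class precision/recall/F1 metric suite.

All metrics derive from one-vs-rest counts on a 5x5 confusion matrix
(rows = true class, columns = predicted class):

    recall_c    = TP_c / (TP_c + FN_c)
    precision_c = TP_c / (TP_c + FP_c)
    F1_c        = 2 * precision_c * recall_c / (precision_c + recall_c)

Overall accuracy is trace/total — the multiclass form of the binary
(TP+TN)/(TP+TN+FP+FN) identity, with which it coincides class-by-class.
A class with an empty denominator gets metric 0 and a warning.  The
support-weighted mean recall equals overall accuracy by construction;
"average" rows in rendered reports are unweighted macro means.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .io import AAMI_CLASSES

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValidationError(f"confusion matrix must be square, got {c.shape}")
        if np.any(c < 0):
            raise ValidationError("confusion matrix counts must be nonnegative")
        self.counts = c.astype(int)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, c: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class ``c``."""
        tp = int(self.counts[c, c])
        fn = int(self.counts[c].sum()) - tp
        fp = int(self.counts[:, c].sum()) - tp
        tn = self.total - tp - fn - fp
        return tp, fp, fn, tn


def confusion(true_labels, predicted_labels, n_classes: int = 5) -> ConfusionMatrix:
    """Tally a confusion matrix from parallel label arrays."""
    y = np.asarray(true_labels, dtype=int).ravel()
    p = np.asarray(predicted_labels, dtype=int).ravel()
    if y.size != p.size:
        raise ValidationError(f"{y.size} true labels vs {p.size} predictions")
    if y.size and (min(y.min(), p.min()) < 0 or max(y.max(), p.max()) >= n_classes):
        raise ValidationError(f"labels must lie in 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (y, p), 1)
    return ConfusionMatrix(counts)


@dataclass
class EvalReport:
    """Per-class and averaged classification metrics, all as fractions."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    cm: ConfusionMatrix

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def _weighted(self, values: np.ndarray) -> float:
        total = self.support.sum()
        return float(values @ self.support / total) if total else 0.0

    @property
    def weighted_precision(self) -> float:
        return self._weighted(self.precision)

    @property
    def weighted_recall(self) -> float:
        return self._weighted(self.recall)

    @property
    def weighted_f1(self) -> float:
        return self._weighted(self.f1)

    def to_frame(self) -> pd.DataFrame:
        """Per-class rows plus a macro-average row, metrics as fractions."""
        classes = list(AAMI_CLASSES[: self.precision.size])
        df = pd.DataFrame({
            "precision": np.append(self.precision, self.macro_precision),
            "recall": np.append(self.recall, self.macro_recall),
            "f1": np.append(self.f1, self.macro_f1),
            "support": np.append(self.support, self.support.sum()),
        }, index=classes + ["average"])
        return df

    def to_dict(self) -> dict:
        return {
            "classes": list(AAMI_CLASSES[: self.precision.size]),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "support": self.support.tolist(),
            "macro": {"precision": self.macro_precision,
                      "recall": self.macro_recall, "f1": self.macro_f1},
            "weighted": {"precision": self.weighted_precision,
                         "recall": self.weighted_recall, "f1": self.weighted_f1},
            "accuracy": self.accuracy,
            "confusion_matrix": self.cm.counts.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(
            precision=np.asarray(d["precision"], dtype=float),
            recall=np.asarray(d["recall"], dtype=float),
            f1=np.asarray(d["f1"], dtype=float),
            support=np.asarray(d["support"], dtype=int),
            accuracy=float(d["accuracy"]),
            cm=ConfusionMatrix(np.asarray(d["confusion_matrix"])),
        )


def metrics(cm: ConfusionMatrix) -> EvalReport:
    """One-vs-rest precision/recall/F1 per class plus overall accuracy."""
    k = cm.n_classes
    precision = np.zeros(k)
    recall = np.zeros(k)
    f1 = np.zeros(k)
    support = cm.counts.sum(axis=1)
    for c in range(k):
        tp, fp, fn, _ = cm.one_vs_rest(c)
        if tp + fp:
            precision[c] = tp / (tp + fp)
        else:
            logger.warning("class %d has no predictions; precision set to 0", c)
        if tp + fn:
            recall[c] = tp / (tp + fn)
        else:
            logger.warning("class %d has no true members; recall set to 0", c)
        if precision[c] + recall[c]:
            f1[c] = 2 * precision[c] * recall[c] / (precision[c] + recall[c])
    accuracy = float(np.trace(cm.counts) / cm.total) if cm.total else 0.0
    return EvalReport(precision=precision, recall=recall, f1=f1,
                      support=support, accuracy=accuracy, cm=cm)


def evaluate_predictions(true_labels, predicted_labels,
                         n_classes: int = 5) -> EvalReport:
    return metrics(confusion(true_labels, predicted_labels, n_classes))


def _pct(x: float) -> int:
    """Percent rounded half-up to an integer, the usual reporting format."""
    return int(np.floor(100.0 * x + 0.5))


def render_report(r: EvalReport) -> tuple[str, str]:
    """Render ``(human_table, machine_json)``.

    The table lists per-class precision/recall/F1 as integer percentages
    with a macro-average column and the overall accuracy, mirroring the
    conventional per-class evaluation layout; the JSON round-trips through
    :meth:`EvalReport.from_dict`.
    """
    classes = list(AAMI_CLASSES[: r.precision.size])
    buf = io.StringIO()
    header = ["metric"] + classes + ["average"]
    rows = [
        ["precision (%)"] + [_pct(v) for v in r.precision] + [_pct(r.macro_precision)],
        ["recall (%)"] + [_pct(v) for v in r.recall] + [_pct(r.macro_recall)],
        ["f1 (%)"] + [_pct(v) for v in r.f1] + [_pct(r.macro_f1)],
    ]
    widths = [max(len(str(row[i])) for row in [header] + rows)
              for i in range(len(header))]
    for row in [header] + rows:
        buf.write("  ".join(str(v).rjust(w) for v, w in zip(row, widths)) + "\n")
    buf.write(f"overall accuracy (%): {_pct(r.accuracy)}\n")
    return buf.getvalue(), json.dumps(r.to_dict(), indent=2)
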