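"""Frame-level evaluation: per-class precision/recall/F1, macro averages, confusion.

All scoring is at frame granularity for both the per-frame model and the
expanded sliding-window output.  Precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2PR/(P+R); any 0/0 denominator yields 0 by convention (small synthetic
folds can miss a class entirely).  Macro averages are unweighted means over all
classes including background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataset import ActivityCatalog

__all__ = [
    "MetricsReport",
    "confusion_matrix",
    "precision_recall_f1",
    "evaluate",
]


def confusion_matrix(
    pred: np.ndarray, truth: np.ndarray, n_classes: int
) -> np.ndarray:
    """``(C, C)`` count matrix; entry (i, j) counts frames with truth i, prediction j."""
    pred = np.asarray(pred, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError(
            f"pred and truth must be equal-length 1-D sequences; got "
            f"{pred.shape} and {truth.shape}"
        )
    for name, a in (("pred", pred), ("truth", truth)):
        if len(a) and ((a < 0).any() or (a >= n_classes).any()):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (truth, pred), 1)
    return cm


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """The three frame-level scores from raw counts; 0/0 -> 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return float(precision), float(recall), float(f1)


@dataclass
class MetricsReport:
    """Frame-level scores derived from a pooled confusion matrix."""

    class_names: tuple[str, ...]
    confusion: np.ndarray  # (C, C), rows true, columns predicted
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    n_frames: int

    @classmethod
    def from_confusion(
        cls, confusion: np.ndarray, class_names: Sequence[str]
    ) -> "MetricsReport":
        cm = np.asarray(confusion, dtype=np.int64)
        C = cm.shape[0]
        tp = np.diag(cm).astype(np.int64)
        fp = cm.sum(axis=0) - tp  # predicted as c but true class differs
        fn = cm.sum(axis=1) - tp  # true class c predicted as something else
        prf = np.array(
            [precision_recall_f1(int(tp[c]), int(fp[c]), int(fn[c])) for c in range(C)]
        )
        return cls(
            class_names=tuple(class_names),
            confusion=cm,
            tp=tp,
            fp=fp,
            fn=fn,
            precision=prf[:, 0],
            recall=prf[:, 1],
            f1=prf[:, 2],
            macro_precision=float(prf[:, 0].mean()),
            macro_recall=float(prf[:, 1].mean()),
            macro_f1=float(prf[:, 2].mean()),
            n_frames=int(cm.sum()),
        )

    @property
    def accuracy(self) -> float:
        """Overall frame accuracy (micro average)."""
        return float(self.tp.sum() / self.n_frames) if self.n_frames else 0.0

    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "accuracy": self.accuracy,
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
            "per_class": {
                name: {
                    "tp": int(self.tp[c]),
                    "fp": int(self.fp[c]),
                    "fn": int(self.fn[c]),
                    "precision": float(self.precision[c]),
                    "recall": float(self.recall[c]),
                    "f1": float(self.f1[c]),
                }
                for c, name in enumerate(self.class_names)
            },
            "confusion": self.confusion.tolist(),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def _as_sequences(x) -> list[np.ndarray]:
    if isinstance(x, np.ndarray) and x.ndim == 1:
        return [x]
    return [np.asarray(s) for s in x]


def evaluate(
    pred, truth, catalog: ActivityCatalog
) -> MetricsReport:
    """Score predictions against truth, pooling frames across samples.

    ``pred`` and ``truth`` are label sequences or matched lists of them.
    """
    preds = _as_sequences(pred)
    truths = _as_sequences(truth)
    if len(preds) != len(truths):
        raise ValueError("pred and truth sample counts differ")
    for i, (p, t) in enumerate(zip(preds, truths)):
        if p.shape != t.shape:
            raise ValueError(f"sample {i}: pred/truth length mismatch")
    cm = confusion_matrix(
        np.concatenate(preds), np.concatenate(truths), catalog.n_classes
    )
    return MetricsReport.from_confusion(cm, catalog.names)
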