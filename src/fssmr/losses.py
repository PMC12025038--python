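"""Loss functions and evaluation metrics for the joint seg+class task.

The segmentation and classification losses share one cross-entropy form:
the negative log of the predicted probability of the true class, averaged
over samples (pixels count as samples for segmentation).  The total
training objective adds an auxiliary term, by default the L2 weight
penalty.  Metrics follow the confusion-count definitions, including the
model family's accuracy-derived error measure MSE = 1 - A^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPS = 1e-12

__all__ = [
    "PredictionBatch",
    "ConfusionCounts",
    "MetricsReport",
    "seg_loss",
    "cross_entropy",
    "total_loss",
    "accuracy",
    "precision_recall_f1",
    "mse_metric",
    "confusion_from_labels",
    "macro_metrics",
]


@dataclass
class PredictionBatch:
    """Per-sample class probabilities and one-hot truths.

    Rows of ``probs`` must be distributions (sum to 1 within 1e-6);
    ``labels`` has exactly one 1 per row.
    """

    probs: np.ndarray  # (N, C)
    labels: np.ndarray  # (N, C) one-hot

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if self.probs.shape != self.labels.shape:
            raise ValueError(
                f"probs shape {self.probs.shape} != labels shape {self.labels.shape}"
            )
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be nonnegative")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"probability row {bad} sums to {sums[bad]:.8f}, not 1"
            )
        if np.any(self.labels.sum(axis=1) != 1):
            raise ValueError("each label row must be one-hot")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """Summary metrics plus loss components for one evaluation pass."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    mse: float
    seg_loss: float = 0.0
    class_loss: float = 0.0
    aux_loss: float = 0.0
    total_loss: float = 0.0
    pixel_accuracy: float = 0.0
    degenerate: bool = False
    per_class: dict = field(default_factory=dict)


def cross_entropy(batch: PredictionBatch) -> float:
    """-(1/N) sum_i sum_c y_ic log p_ic, natural log, probs clamped to [eps, 1]."""
    p = np.clip(batch.probs, EPS, 1.0)
    return float(-(batch.labels * np.log(p)).sum() / batch.probs.shape[0])


def seg_loss(batch: PredictionBatch) -> float:
    """Per-pixel cross-entropy; pixels are the samples of the average."""
    return cross_entropy(batch)


def total_loss(seg: float, class_: float, aux: float = 0.0) -> float:
    """Seg + Class + Auxiliary; with aux = 0 the plain two-term objective."""
    for name, v in (("seg", seg), ("class", class_), ("aux", aux)):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} loss component must be finite and >= 0, got {v}")
    return seg + class_ + aux


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / total."""
    if counts.total == 0:
        raise ValueError("accuracy undefined for zero total predictions")
    return (counts.TP + counts.TN) / counts.total


def precision_recall_f1(counts: ConfusionCounts) -> tuple[float, float, float, bool]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R).

    A zero denominator yields the sentinel value 0 and sets the returned
    ``degenerate`` flag instead of raising.
    """
    degenerate = False
    if counts.TP + counts.FP == 0:
        precision, degenerate = 0.0, True
    else:
        precision = counts.TP / (counts.TP + counts.FP)
    if counts.TP + counts.FN == 0:
        recall, degenerate = 0.0, True
    else:
        recall = counts.TP / (counts.TP + counts.FN)
    if precision + recall == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1, degenerate


def mse_metric(A: float) -> float:
    """Accuracy-derived error 1 - A^2; monotone decreasing in A on [0, 1]."""
    if not 0.0 <= A <= 1.0:
        raise ValueError(f"accuracy must lie in [0, 1], got {A}")
    return 1.0 - A**2


def confusion_from_labels(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> np.ndarray:
    """Full confusion matrix, rows = truth, cols = prediction."""
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def one_vs_rest_counts(cm: np.ndarray, cls: int) -> ConfusionCounts:
    tp = int(cm[cls, cls])
    fp = int(cm[:, cls].sum() - tp)
    fn = int(cm[cls, :].sum() - tp)
    tn = int(cm.sum() - tp - fp - fn)
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def macro_metrics(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> MetricsReport:
    """Multi-class report: correct/total accuracy, macro one-vs-rest P/R/F1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    cm = confusion_from_labels(y_true, y_pred, n_classes)
    acc = float(np.trace(cm) / cm.sum())
    per_class = {}
    ps, rs = [], []
    degenerate = False
    for c in range(n_classes):
        p, r, f, d = precision_recall_f1(one_vs_rest_counts(cm, c))
        per_class[c] = {"precision": p, "recall": r, "f1": f}
        ps.append(p)
        rs.append(r)
        degenerate |= d
    macro_p, macro_r = float(np.mean(ps)), float(np.mean(rs))
    # report-level F1 is the harmonic mean of the report's own P and R
    macro_f = (
        2 * macro_p * macro_r / (macro_p + macro_r) if macro_p + macro_r else 0.0
    )
    return MetricsReport(
        accuracy=acc,
        precision=macro_p,
        recall=macro_r,
        f1=macro_f,
        mse=mse_metric(acc),
        degenerate=degenerate,
        per_class=per_class,
    )
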