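"""Classifier evaluation: confusion counts, precision/recall/F, ROC and PR areas.

Cases are the positive class throughout.  ROC AUC uses the midrank (Mann–
Whitney) convention for ties; the precision–recall area is the average
precision — the step-wise sum ``sum_i (R_i - R_{i-1}) * P_i`` over descending
score thresholds, with no linear interpolation between points (linear PR
interpolation is known to be optimistic).  Zero-denominator conventions:
precision is 0 when nothing is predicted positive, F is 0 when precision and
recall are both 0 — reports stay total on degenerate inputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .datasets import CASE, ExpressionMatrix, MiRPSModel
from .errors import ConfigurationError
from .scoring import score_samples


@dataclass(frozen=True)
class EvaluationReport:
    """Fixed-threshold confusion counts plus threshold-free curve areas."""

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f_score: float
    roc_auc: float
    pr_auc: float
    threshold: float

    @property
    def n_samples(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return asdict(self)


def _as_binary(labels) -> np.ndarray:
    return (np.asarray(labels, dtype=object) == CASE).astype(int)


def confusion_counts(predicted, truth) -> tuple[int, int, int, int]:
    """``(tp, fp, tn, fn)`` with ``case`` as the positive class."""
    pred = _as_binary(predicted)
    true = _as_binary(truth)
    if pred.shape != true.shape:
        raise ConfigurationError(
            f"predicted and true labels differ in length: {pred.shape} vs {true.shape}"
        )
    tp = int(((pred == 1) & (true == 1)).sum())
    fp = int(((pred == 1) & (true == 0)).sum())
    tn = int(((pred == 0) & (true == 0)).sum())
    fn = int(((pred == 0) & (true == 1)).sum())
    return tp, fp, tn, fn


def precision_recall_fscore(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float, float]:
    """Precision ``tp/(tp+fp)``, recall ``tp/(tp+fn)``, F ``2pr/(p+r)``."""
    if min(tp, fp, tn, fn) < 0:
        raise ConfigurationError("confusion counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f_score = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0 else 0.0
    )
    return precision, recall, f_score


def roc_auc(scores, truth) -> float:
    """Area under the ROC curve.

    Equals the Mann–Whitney U statistic normalized by ``n_case * n_control``
    (ties contribute one half); invariant under strictly increasing score
    transforms.
    """
    y = _as_binary(truth)
    if y.min() == y.max():
        raise ConfigurationError("roc_auc: both classes must be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def pr_auc(scores, truth) -> float:
    """Average precision: step-wise area under the precision-recall curve."""
    y = _as_binary(truth)
    if y.sum() == 0:
        raise ConfigurationError("pr_auc: no positive samples")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def evaluate(model: MiRPSModel, matrix: ExpressionMatrix) -> EvaluationReport:
    """Score ``matrix`` with ``model`` and report all metrics at its threshold."""
    if matrix.labels is None:
        raise ConfigurationError("labels: evaluation requires a labeled matrix")
    table = score_samples(model, matrix)
    tp, fp, tn, fn = confusion_counts(table["label"].to_numpy(), matrix.labels)
    precision, recall, f_score = precision_recall_fscore(tp, fp, tn, fn)
    return EvaluationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        precision=precision, recall=recall, f_score=f_score,
        roc_auc=roc_auc(table["score"].to_numpy(), matrix.labels),
        pr_auc=pr_auc(table["score"].to_numpy(), matrix.labels),
        threshold=model.threshold,
    )


def curve_points(scores, truth) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """ROC and PR curve coordinates for external plotting.

    Returns ``(fpr, tpr, precision, recall)`` arrays over descending score
    thresholds.
    """
    from sklearn.metrics import precision_recall_curve, roc_curve

    y = _as_binary(truth)
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    precision, recall, _ = precision_recall_curve(y, np.asarray(scores, dtype=float))
    return fpr, tpr, precision, recall
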