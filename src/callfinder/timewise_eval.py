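"""Time-wise and frame-wise comparison of machine output against ground truth.

Ground-truth intervals closer than a merging factor ``xi`` (default half the
prediction window) are combined before scoring, because a sliding window
straddling such a gap still contains mostly vocalization.  For precision,
each merged interval is additionally extended by ``lambda`` at both borders
to forgive predictions overhanging annotation edges.  Both metrics are
duration-weighted: precision is the fraction of predicted time lying inside
the extended ground truth, recall the fraction of (unextended) merged
ground-truth time covered by predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .segmentation import Annotation, FrameScore

__all__ = [
    "TimewiseEvalConfig",
    "merge_ground_truth",
    "timewise_precision_recall",
    "frame_roc_auc",
    "confusion_and_uar",
]


@dataclass(frozen=True)
class TimewiseEvalConfig:
    merge_xi: float
    extend_lambda: float

    def __post_init__(self) -> None:
        if self.merge_xi < 0 or self.extend_lambda < 0:
            raise ValueError("merge_xi and extend_lambda must be >= 0")

    @classmethod
    def from_window(cls, window_length_epsilon: float) -> "TimewiseEvalConfig":
        """The default parameterization: xi = lambda = epsilon / 2."""
        return cls(merge_xi=window_length_epsilon / 2, extend_lambda=window_length_epsilon / 2)


def _as_intervals(annotations: Sequence[Annotation]) -> List[Tuple[float, float]]:
    return sorted((a.start, a.end) for a in annotations)


def _union(intervals: Sequence[Tuple[float, float]], gap: float = 0.0) -> List[Tuple[float, float]]:
    """Union of intervals, additionally merging gaps of at most ``gap``."""
    merged: List[Tuple[float, float]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + gap + 1e-12:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _total(intervals: Sequence[Tuple[float, float]]) -> float:
    return float(sum(e - s for s, e in intervals))


def _intersection_length(
    a: Sequence[Tuple[float, float]], b: Sequence[Tuple[float, float]]
) -> float:
    total = 0.0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0.0, min(e1, e2) - max(s1, s2))
    return total


def merge_ground_truth(
    gt: Sequence[Annotation], cfg: TimewiseEvalConfig
) -> List[Annotation]:
    """Transitively combine annotations whose gap is at most ``xi``."""
    if not gt:
        return []
    label = gt[0].label
    merged = _union(_as_intervals(gt), gap=cfg.merge_xi)
    return [Annotation(start=s, end=e, label=label) for s, e in merged]


def timewise_precision_recall(
    pred: Sequence[Annotation],
    gt: Sequence[Annotation],
    cfg: TimewiseEvalConfig,
    recording_bounds: Optional[Tuple[float, float]] = None,
) -> Tuple[Optional[float], Optional[float]]:
    """Duration-weighted (PREC, TPR) of predictions against ground truth.

    Ground truth is xi-merged first.  Precision measures predicted time
    inside the lambda-extended merged ground truth; recall measures merged
    (unextended) ground-truth time covered by predictions.  Extensions are
    clipped to ``recording_bounds`` when given.  An empty prediction list
    gives ``(None, 0.0)``; empty ground truth gives ``(0.0, None)``.
    """
    pred_union = _union(_as_intervals(pred))
    merged = _union(_as_intervals(gt), gap=cfg.merge_xi)

    if not pred_union and not merged:
        return None, None
    if not merged:
        return 0.0, None
    if not pred_union:
        return None, 0.0

    lam = cfg.extend_lambda
    extended = [(s - lam, e + lam) for s, e in merged]
    if recording_bounds is not None:
        lo, hi = recording_bounds
        extended = [(max(s, lo), min(e, hi)) for s, e in extended]
    extended = _union(extended)

    prec = _intersection_length(pred_union, extended) / _total(pred_union)
    tpr = _intersection_length(pred_union, merged) / _total(merged)
    return prec, tpr


def frame_ground_truth(
    frames: Sequence[FrameScore], gt: Sequence[Annotation], cfg: Optional[TimewiseEvalConfig] = None
) -> np.ndarray:
    """Binary per-frame labels: positive iff at least half the frame overlaps
    the (optionally xi-merged) ground truth."""
    gap = cfg.merge_xi if cfg is not None else 0.0
    merged = _union(_as_intervals(gt), gap=gap)
    labels = np.zeros(len(frames), dtype=bool)
    for i, frame in enumerate(frames):
        overlap = _intersection_length([(frame.start, frame.end)], merged)
        labels[i] = overlap >= 0.5 * (frame.end - frame.start)
    return labels


def frame_roc_auc(
    frames: Sequence[FrameScore],
    gt: Sequence[Annotation],
    target_class: str = "target",
    cfg: Optional[TimewiseEvalConfig] = None,
) -> Tuple[np.ndarray, Optional[float]]:
    """ROC points swept over the confidence threshold, and the trapezoid AUC.

    Frames are labeled against ground truth by majority overlap; the sweep
    visits every distinct score as a threshold (score > delta is positive).
    With rank-averaged tie handling this AUC equals the Mann-Whitney rank
    statistic.  Single-class ground truth yields ``(points, None)``.
    """
    labels = frame_ground_truth(frames, gt, cfg)
    scores = np.array([f.probs[target_class] for f in frames], dtype=float)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    points = [(0.0, 0.0)]
    thresholds = np.unique(scores)[::-1]
    for thr in thresholds:
        predicted = scores >= thr
        tpr = float((predicted & labels).sum()) / n_pos if n_pos else 0.0
        fpr = float((predicted & ~labels).sum()) / n_neg if n_neg else 0.0
        points.append((fpr, tpr))
    points.append((1.0, 1.0))
    roc = np.array(sorted(set(points)))
    if n_pos == 0 or n_neg == 0:
        return roc, None
    auc = float(np.trapezoid(roc[:, 1], roc[:, 0]))
    return roc, auc


def confusion_and_uar(
    pairs: Sequence[Tuple[str, str]], classes: Sequence[str]
) -> Tuple[np.ndarray, float]:
    """Confusion matrix (rows = true classes) and unweighted average recall.

    Classes without any true sample are excluded from the UAR mean with a
    warning; classes whose recall is zero but that do occur are included.
    """
    if not pairs:
        raise ValueError("confusion_and_uar requires at least one (true, pred) pair")
    classes = list(classes)
    y_true = [t for t, _ in pairs]
    y_pred = [p for _, p in pairs]
    matrix = _sk_confusion(y_true, y_pred, labels=classes)
    support = matrix.sum(axis=1)
    if np.any(support == 0):
        missing = [c for c, s in zip(classes, support) if s == 0]
        warnings.warn(f"classes without true samples excluded from UAR: {missing}")
    recalls = [matrix[i, i] / support[i] for i in range(len(classes)) if support[i] > 0]
    return matrix, float(np.mean(recalls))
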