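"""Evaluation metrics: detection PR/AP, landmark and curve distances,
pixel-classification scores, regression agreement and table aggregation.

Notes on conventions. L1 landmark distances use absolute coordinate
differences (|dx| + |dy|): a signed sum is not a distance. AP uses
all-point interpolation (the precision envelope integrated over recall
steps). F1 and the Dice coefficient computed from one confusion-count set
are algebraically identical, and the package asserts that identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.spatial.distance import directed_hausdorff
from scipy.stats import linregress

from .core import BMOPair, CornerBox, scale_xy
from .detect import iou

logger = logging.getLogger(__name__)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero to ``ndigits`` decimals (table convention).

    The value is first quantised at 10 decimals so that a binary float
    sitting a hair below an exact decimal half (e.g. 39.224999999999994
    for the decimal mean 39.225) still rounds up as the decimal would.
    """
    d = Decimal(repr(float(value))).quantize(Decimal("1e-10"), rounding=ROUND_HALF_UP)
    return float(d.quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN counts over a set of evaluated units (pixels or boxes)."""

    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def precision_recall(c: ConfusionCounts) -> tuple[float, float]:
    """(precision, recall); empty denominators yield 0 by convention."""
    if c.tp + c.fp == 0:
        logger.debug("precision denominator empty; returning 0")
        p = 0.0
    else:
        p = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        logger.debug("recall denominator empty; returning 0")
        r = 0.0
    else:
        r = c.tp / (c.tp + c.fn)
    return p, r


def classification_scores(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, F1, Dice). F1 == Dice for any single count set."""
    if c.total == 0:
        raise ValueError("cannot score an empty count set")
    accuracy = (c.tp + c.tn) / c.total
    p, r = precision_recall(c)
    f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    dice = 0.0 if 2 * c.tp + c.fp + c.fn == 0 else 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    return accuracy, f1, dice


@dataclass
class RankedDetections:
    """Score-ranked detections with per-detection match flags.

    ``matched`` marks detections matched one-to-one to a ground-truth box;
    ``n_ground_truth`` is the number of ground-truth boxes of the class.
    """

    scores: np.ndarray
    matched: np.ndarray
    n_ground_truth: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.matched = np.asarray(self.matched, dtype=bool)
        if self.scores.shape != self.matched.shape:
            raise ValueError("scores and matched must align")
        if int(self.matched.sum()) > self.n_ground_truth:
            raise ValueError("cannot match more detections than ground-truth boxes")


def average_precision(d: RankedDetections) -> float:
    """Area under the precision–recall curve, all-point interpolation."""
    if d.n_ground_truth == 0:
        raise ValueError("average precision undefined without ground-truth boxes")
    if len(d.scores) == 0:
        return 0.0
    order = np.argsort(-d.scores, kind="stable")
    matched = d.matched[order]
    tp = np.cumsum(matched)
    fp = np.cumsum(~matched)
    recall = tp / d.n_ground_truth
    precision = tp / (tp + fp)
    # precision envelope: running maximum from the right
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - r_prev) * env))


def mean_ap(aps: list[float]) -> float:
    """Mean AP over classes."""
    if not aps:
        raise ValueError("need at least one per-class AP")
    return float(np.mean(aps))


def match_detections(
    predictions: list[tuple[CornerBox, float]],
    truths: list[CornerBox],
    iou_threshold: float = 0.5,
) -> RankedDetections:
    """Greedy one-to-one matching by descending score at the given IoU."""
    preds = sorted(predictions, key=lambda bs: -bs[1])
    used = np.zeros(len(truths), dtype=bool)
    matched = np.zeros(len(preds), dtype=bool)
    for i, (box, _) in enumerate(preds):
        best_j, best_iou = -1, iou_threshold
        for j, gt in enumerate(truths):
            if used[j] or gt.label != box.label:
                continue
            val = iou(box, gt)
            if val >= best_iou:
                best_j, best_iou = j, val
        if best_j >= 0:
            used[best_j] = True
            matched[i] = True
    return RankedDetections(
        scores=np.array([s for _, s in preds]),
        matched=matched,
        n_ground_truth=sum(1 for t in truths),
    )


def landmark_distances(pred: BMOPair, truth: BMOPair, scale) -> dict[str, float]:
    """Per-side and combined L1/L2 landmark distances in μm.

    L1 = |dx| + |dy|, L2 = sqrt(dx² + dy²), with dx, dy scaled per axis;
    combined values are the means of the two sides.
    """
    sx, sy = scale_xy(scale)
    out: dict[str, float] = {}
    for side, p, t in (("left", pred.left, truth.left), ("right", pred.right, truth.right)):
        dx = (p[0] - t[0]) * sx
        dy = (p[1] - t[1]) * sy
        out[f"{side}_L1"] = abs(dx) + abs(dy)
        out[f"{side}_L2"] = float(np.hypot(dx, dy))
    out["combined_L1"] = (out["left_L1"] + out["right_L1"]) / 2.0
    out["combined_L2"] = (out["left_L2"] + out["right_L2"]) / 2.0
    return out


def curve_distances(
    pred: np.ndarray, truth: np.ndarray, scale
) -> tuple[float, float]:
    """(mean y-difference, Hausdorff distance) between two curves, in μm.

    The mean y-difference averages |y_pred − y_truth| over the shared
    x-support; the Hausdorff distance is the symmetric max of the two
    directed max–min point distances over the full point sets.
    """
    sx, sy = scale_xy(scale)
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    p_um = pred * [sx, sy]
    t_um = truth * [sx, sy]
    hausdorff = max(
        directed_hausdorff(p_um, t_um)[0], directed_hausdorff(t_um, p_um)[0]
    )
    shared, pi, ti = np.intersect1d(pred[:, 0], truth[:, 0], return_indices=True)
    if len(shared) == 0:
        raise ValueError("curves share no x-support; mean y-difference undefined")
    mean_y = float(np.mean(np.abs(pred[pi, 1] - truth[ti, 1])) * sy)
    return mean_y, float(hausdorff)


def regression_r2(pred, truth) -> float:
    """Coefficient of determination of the OLS fit of pred against truth."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1 or len(pred) < 2:
        raise ValueError("pred and truth must be equal-length 1-D with n >= 2")
    if np.var(truth) == 0 or np.var(pred) == 0:
        raise ValueError("zero variance; R^2 undefined")
    return float(linregress(truth, pred).rvalue ** 2)


def aggregate_table(rows) -> list[float]:
    """Column-wise arithmetic mean, rounded half-up to 2 decimals.

    ``rows`` is a sequence of equal-length numeric rows (per-plane or
    per-side table rows); returns the summary row.
    """
    arr = np.asarray(rows, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty table")
    arr = np.atleast_2d(arr)
    # average in decimal space: table cells are printed decimals, and the
    # binary mean can sit epsilon below an exact decimal half
    out = []
    for col in arr.T:
        mean = sum(Decimal(repr(float(v))) for v in col) / len(col)
        out.append(float(mean.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)))
    return out
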