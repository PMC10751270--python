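"""Evaluation metrics: box IoU and average precision, landmark error
normalized by interocular distance, head-pose MAE, and binary F1.

Average precision follows the detection-benchmark convention: predictions
are ranked by descending confidence (score ties broken by input order),
greedily matched to the highest-IoU unmatched ground-truth box of the same
image at an IoU threshold, and the precision-recall staircase is integrated
point by point (all-points rule, no precision interpolation envelope).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import UndefinedMetricError
from .geometry import BoundingBox, HeadPose, LandmarkSet68, interocular_distance

__all__ = [
    "DetectionSet",
    "iou",
    "average_precision",
    "landmark_nme",
    "pose_mae",
    "f1_binary",
]


@dataclass
class DetectionSet:
    """Scored predictions and ground-truth boxes, keyed by image identifier."""

    pred_boxes: list
    pred_image_ids: list
    gt_boxes: list
    gt_image_ids: list

    def __post_init__(self):
        if len(self.pred_boxes) != len(self.pred_image_ids):
            raise ValueError("pred_boxes and pred_image_ids must align")
        if len(self.gt_boxes) != len(self.gt_image_ids):
            raise ValueError("gt_boxes and gt_image_ids must align")
        for b in list(self.pred_boxes) + list(self.gt_boxes):
            if not isinstance(b, BoundingBox):
                raise TypeError("boxes must be BoundingBox instances")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes, in [0, 1]."""
    ix = max(0.0, min(a.right, b.right) - max(a.x, b.x))
    iy = max(0.0, min(a.bottom, b.bottom) - max(a.y, b.y))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def average_precision(dets: DetectionSet, iou_threshold: float = 0.5) -> float:
    """Area under the exact precision-recall staircase.

    Raises :class:`UndefinedMetricError` when there is no ground truth.
    """
    n_gt = len(dets.gt_boxes)
    if n_gt == 0:
        raise UndefinedMetricError("average precision undefined without ground truth")
    if len(dets.pred_boxes) == 0:
        return 0.0
    scores = np.array([b.score for b in dets.pred_boxes])
    order = np.argsort(-scores, kind="stable")  # ties keep input order
    gt_by_image: dict = {}
    for i, img in enumerate(dets.gt_image_ids):
        gt_by_image.setdefault(img, []).append(i)
    matched = set()
    tp = np.zeros(len(order))
    for rank, pi in enumerate(order):
        img = dets.pred_image_ids[pi]
        best_iou, best_gt = 0.0, None
        for gi in gt_by_image.get(img, []):
            if gi in matched:
                continue
            o = iou(dets.pred_boxes[pi], dets.gt_boxes[gi])
            if o > best_iou:
                best_iou, best_gt = o, gi
        if best_gt is not None and best_iou >= iou_threshold:
            matched.add(best_gt)
            tp[rank] = 1.0
    cum_tp = np.cumsum(tp)
    precision = cum_tp / (np.arange(len(order)) + 1)
    recall = cum_tp / n_gt
    prev_r = 0.0
    ap = 0.0
    for p, r in zip(precision, recall):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def landmark_nme(pred: LandmarkSet68, gt: LandmarkSet68) -> float:
    """RMSE over the 68 point-wise Euclidean errors, divided by the
    ground-truth interocular distance."""
    d = np.linalg.norm(pred.points - gt.points, axis=1)
    rmse = float(np.sqrt(np.mean(d ** 2)))
    return rmse / interocular_distance(gt)


def pose_mae(pred, gt) -> tuple[float, float, float, float]:
    """Per-axis mean absolute error in degrees: (pitch, roll, yaw, average)."""
    pred, gt = list(pred), list(gt)
    if len(pred) != len(gt) or len(pred) == 0:
        raise ValueError("pred and gt pose lists must have equal nonzero length")
    P = np.array([p.as_array() for p in pred])
    G = np.array([g.as_array() for g in gt])
    mae = np.abs(P - G).mean(axis=0)
    return float(mae[0]), float(mae[1]), float(mae[2]), float(mae.mean())


def f1_binary(pred, gt) -> float:
    """F1 = 2TP / (2TP + FP + FN); 0 when there are no true positives.

    Raises :class:`UndefinedMetricError` when the ground truth has no
    positive instances.
    """
    p = np.asarray(pred).astype(int).ravel()
    g = np.asarray(gt).astype(int).ravel()
    if p.shape != g.shape:
        raise ValueError("pred and gt must have equal length")
    if g.sum() == 0:
        raise UndefinedMetricError("F1 undefined: ground truth has no positives")
    tp = int(np.sum((p == 1) & (g == 1)))
    fp = int(np.sum((p == 1) & (g == 0)))
    fn = int(np.sum((p == 0) & (g == 1)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0
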