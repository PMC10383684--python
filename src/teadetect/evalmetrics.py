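"""Detection evaluation: greedy matching, P/R/F1, PR curves, AP, NMS.

Boxes are xyxy, 0-based half-open pixel coordinates.  Matching is greedy
one-to-one: detections in descending score order each claim the unmatched
ground truth of highest IoU at or above the threshold.  AP uses 101-point
interpolation of the precision-recall curve; mAP@[0.5:0.95] averages AP
over IoU thresholds 0.50 to 0.95 in steps of 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectionSet",
    "PRCurve",
    "box_iou",
    "nms",
    "match_detections",
    "precision_recall_f1",
    "average_precision",
    "mean_ap",
    "evaluate",
]


@dataclass
class DetectionSet:
    boxes: np.ndarray  # (M, 4) xyxy
    scores: np.ndarray  # (M,)
    image_id: str = ""

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(-1, 4)
        self.scores = np.asarray(self.scores, dtype=np.float64).reshape(-1)
        if len(self.boxes) and (
            np.any(self.boxes[:, 2] <= self.boxes[:, 0])
            or np.any(self.boxes[:, 3] <= self.boxes[:, 1])
        ):
            raise ValueError("detection boxes must satisfy x2 > x1, y2 > y1")

    def sorted(self) -> "DetectionSet":
        order = np.argsort(-self.scores, kind="stable")
        return DetectionSet(self.boxes[order], self.scores[order], self.image_id)


@dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray
    interpolated: np.ndarray
    ap: float


def box_iou(boxes1, boxes2) -> np.ndarray:
    """Pairwise IoU matrix between (M, 4) and (N, 4) xyxy boxes."""
    b1 = np.asarray(boxes1, dtype=np.float64).reshape(-1, 4)
    b2 = np.asarray(boxes2, dtype=np.float64).reshape(-1, 4)
    ix = np.maximum(
        0.0,
        np.minimum(b1[:, None, 2], b2[None, :, 2])
        - np.maximum(b1[:, None, 0], b2[None, :, 0]),
    )
    iy = np.maximum(
        0.0,
        np.minimum(b1[:, None, 3], b2[None, :, 3])
        - np.maximum(b1[:, None, 1], b2[None, :, 1]),
    )
    inter = ix * iy
    a1 = (b1[:, 2] - b1[:, 0]) * (b1[:, 3] - b1[:, 1])
    a2 = (b2[:, 2] - b2[:, 0]) * (b2[:, 3] - b2[:, 1])
    union = a1[:, None] + a2[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms(boxes, scores, iou_threshold: float) -> np.ndarray:
    """Greedy suppression; returns kept indices, stable ties by index."""
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    order = np.lexsort((np.arange(len(scores)), -scores))
    keep = []
    suppressed = np.zeros(len(scores), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        suppressed[i] = True
        rest = order[~suppressed[order]]
        if len(rest):
            ious = box_iou(boxes[i : i + 1], boxes[rest])[0]
            suppressed[rest[ious > iou_threshold]] = True
    return np.array(keep, dtype=np.int64)


def match_detections(dets: DetectionSet, gts, iou_threshold: float = 0.5):
    """One image's greedy matching -> (TP, FP, FN, per-detection flags)."""
    gts = np.asarray(gts, dtype=np.float64).reshape(-1, 4)
    d = dets.sorted()
    flags = np.zeros(len(d.boxes), dtype=bool)
    taken = np.zeros(len(gts), dtype=bool)
    if len(d.boxes) and len(gts):
        ious = box_iou(d.boxes, gts)
        for i in range(len(d.boxes)):
            cand = np.where(~taken & (ious[i] >= iou_threshold))[0]
            if len(cand):
                best = cand[np.argmax(ious[i, cand])]
                taken[best] = True
                flags[i] = True
    tp = int(flags.sum())
    fp = int(len(flags) - tp)
    fn = int(len(gts) - tp)
    return tp, fp, fn, flags


def precision_recall_f1(tp: int, fp: int, fn: int):
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R)."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp == fp == fn == 0:
        warnings.warn("all counts zero; returning zeros")
        return 0.0, 0.0, 0.0
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (accepts 0-1 or percent)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def average_precision(dets_per_image: dict, gts_per_image: dict,
                      iou_threshold: float = 0.5, n_points: int = 101) -> PRCurve:
    """Pooled score-sweep AP with 101-point interpolation.

    ``dets_per_image`` maps image id -> DetectionSet, ``gts_per_image`` maps
    image id -> (G, 4) array.
    """
    n_gt = sum(len(np.atleast_2d(g)) if len(g) else 0 for g in gts_per_image.values())
    if n_gt == 0:
        raise ValueError("no ground-truth boxes: AP undefined")
    scores, flags = [], []
    for img_id, dets in dets_per_image.items():
        gts = gts_per_image.get(img_id, np.zeros((0, 4)))
        _, _, _, fl = match_detections(dets, gts, iou_threshold)
        scores.append(dets.sorted().scores)
        flags.append(fl)
    if scores:
        scores = np.concatenate(scores)
        flags = np.concatenate(flags)
    else:
        scores, flags = np.zeros(0), np.zeros(0, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    flags = flags[order]
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    # precision envelope, evaluated on an even recall grid
    grid = np.linspace(0, 1, n_points)
    if len(recall) == 0:
        return PRCurve(grid, np.zeros(n_points), np.zeros(n_points), 0.0)
    env = np.maximum.accumulate(precision[::-1])[::-1]
    interp = np.zeros(n_points)
    idx = np.searchsorted(recall, grid, side="left")
    valid = idx < len(recall)
    interp[valid] = env[idx[valid]]
    return PRCurve(recall, precision, interp, float(interp.mean()))


def mean_ap(dets_per_image: dict, gts_per_image: dict,
            thresholds=None) -> float:
    """mAP over IoU thresholds (default the 0.50:0.05:0.95 ladder)."""
    if thresholds is None:
        thresholds = np.arange(0.5, 0.96, 0.05)
    return float(
        np.mean(
            [average_precision(dets_per_image, gts_per_image, t).ap for t in thresholds]
        )
    )


def evaluate(dets_per_image: dict, gts_per_image: dict,
             iou_threshold: float = 0.5) -> dict:
    """Dataset-level P/R/F1 at one threshold plus AP50 and AP[50:95]."""
    tp = fp = fn = 0
    for img_id, gts in gts_per_image.items():
        dets = dets_per_image.get(img_id, DetectionSet(np.zeros((0, 4)), np.zeros(0)))
        t, f, n, _ = match_detections(dets, gts, iou_threshold)
        tp, fp, fn = tp + t, fp + f, fn + n
    p, r, f1 = precision_recall_f1(tp, fp, fn) if tp + fp + fn else (0.0, 0.0, 0.0)
    ap50 = average_precision(dets_per_image, gts_per_image, 0.5).ap
    ap5095 = mean_ap(dets_per_image, gts_per_image)
    return {"P": p, "R": r, "F1": f1, "AP50": ap50, "AP50_95": ap5095,
            "TP": tp, "FP": fp, "FN": fn}
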