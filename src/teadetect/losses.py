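"""Training losses and task-aligned label assignment.

The composite detection loss has three parts:

* **VFL** (varifocal loss) on the classification logits — positives are
  weighted by their IoU-aware target score q, negatives focally
  down-weighted:  q>0: -q(q log p + (1-q) log(1-p));  q=0: -a p^g log(1-p).
* **DFL** (distribution focal loss) on the per-side distance bins — cross
  entropy against the two integer bins bracketing the continuous target y,
  with weights (y_{i+1}-y) and (y-y_i).
* **CIoU** box loss, 1 - CIoU, where CIoU = IoU - rho^2/c^2 - alpha*v with
  the aspect-ratio term v = (4/pi^2)(arctan(w_gt/h_gt) - arctan(w/h))^2 and
  alpha = v / ((1-IoU) + v).

Positive anchors are chosen by the task-aligned rule t = s^alpha * u^beta
(classification score s, IoU u): per ground-truth box, the top-k anchors by
t among those whose cell center lies inside the box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, as_tensor

__all__ = [
    "varifocal_loss",
    "dfl_loss",
    "ciou",
    "ciou_xyxy",
    "task_aligned_assign",
    "detection_loss",
    "BoxPair",
    "LossConfig",
]

_EPS = 1e-7


@dataclass
class LossConfig:
    box_gain: float = 7.5
    cls_gain: float = 0.5
    dfl_gain: float = 1.5
    assigner_alpha: float = 0.5
    assigner_beta: float = 6.0
    assigner_topk: int = 10
    vfl_alpha: float = 0.75
    vfl_gamma: float = 2.0


@dataclass
class BoxPair:
    """Predicted vs ground-truth box, both as (cx, cy, w, h) in pixels."""

    pred: tuple
    gt: tuple


def varifocal_loss(p, q, alpha: float = 0.75, gamma: float = 2.0):
    """Asymmetric IoU-aware classification loss (natural logs).

    ``p`` is the predicted IoU-aware classification score in (0, 1), ``q``
    the target score in [0, 1].  Scalar or array-valued.
    """
    p = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1 - _EPS)
    q = np.asarray(q, dtype=np.float64)
    pos = -q * (q * np.log(p) + (1 - q) * np.log(1 - p))
    neg = -alpha * p**gamma * np.log(1 - p)
    out = np.where(q > 0, pos, neg)
    return float(out) if out.ndim == 0 else out


def dfl_loss(y, s_i, s_i1, y_i=None):
    """Cross entropy against the two bins bracketing the target ``y``.

    ``y_i`` defaults to floor(y); ``s_i`` / ``s_i1`` are the predicted
    probabilities of bins y_i and y_i + 1.
    """
    y = float(y)
    yi = np.floor(y) if y_i is None else float(y_i)
    if not (yi <= y <= yi + 1):
        raise ValueError("y_i must bracket y")
    s_i = max(float(s_i), _EPS)
    s_i1 = max(float(s_i1), _EPS)
    return -((yi + 1 - y) * np.log(s_i) + (y - yi) * np.log(s_i1))


def _ciou_terms(b1, b2):
    """CIoU on tensors of xyxy boxes (broadcastable leading dims)."""
    pi2 = np.float32(np.pi**2)
    x11, y11, x12, y12 = (b1[..., i] for i in range(4))
    x21, y21, x22, y22 = (b2[..., i] for i in range(4))
    w1, h1 = x12 - x11, y12 - y11
    w2, h2 = x22 - x21, y22 - y21
    inter_w = (x12.minimum(x22) - x11.maximum(x21)).clip(0, np.inf)
    inter_h = (y12.minimum(y22) - y11.maximum(y21)).clip(0, np.inf)
    inter = inter_w * inter_h
    union = w1 * h1 + w2 * h2 - inter
    iou = inter / (union + _EPS)
    # normalized center distance
    rho2 = ((x11 + x12 - x21 - x22) ** 2 + (y11 + y12 - y21 - y22) ** 2) * 0.25
    cw = x12.maximum(x22) - x11.minimum(x21)
    ch = y12.maximum(y22) - y11.minimum(y21)
    c2 = cw**2 + ch**2 + _EPS
    v = (4.0 / pi2) * (
        (w2 / (h2 + _EPS)).arctan() - (w1 / (h1 + _EPS)).arctan()
    ) ** 2
    alpha = v / ((1.0 - iou) + v + _EPS)
    return iou - rho2 / c2 - Tensor(alpha.data) * v, iou


def ciou_xyxy(box1, box2):
    """CIoU between xyxy boxes (numpy in, float/array out)."""
    b1 = np.asarray(box1, dtype=np.float64)
    b2 = np.asarray(box2, dtype=np.float64)
    if np.any(b1[..., 2:] <= b1[..., :2]) or np.any(b2[..., 2:] <= b2[..., :2]):
        raise ValueError("degenerate box: zero or negative extent")
    val, _ = _ciou_terms(as_tensor(b1), as_tensor(b2))
    out = val.data
    return float(out) if out.ndim == 0 else out


def ciou(pair: BoxPair) -> float:
    """CIoU of a center-format :class:`BoxPair`."""

    def to_xyxy(b):
        cx, cy, w, h = b
        if w <= 0 or h <= 0:
            raise ValueError("degenerate box: non-positive width/height")
        return (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)

    return ciou_xyxy(to_xyxy(pair.pred), to_xyxy(pair.gt))


def alignment_metric(s, u, alpha: float = 0.5, beta: float = 6.0):
    """Task-alignment degree t = s^alpha * u^beta."""
    return np.asarray(s, dtype=np.float64) ** alpha * np.asarray(u, dtype=np.float64) ** beta


def task_aligned_assign(scores, ious, anchor_points, gt_boxes,
                        alpha: float = 0.5, beta: float = 6.0, topk: int = 10):
    """Select positive anchors per ground-truth box.

    Parameters
    ----------
    scores : (A,) predicted class scores in [0, 1] (single class)
    ious : (A, G) IoU of each anchor's decoded box with each GT
    anchor_points : (A, 2) cell-center coordinates in pixels
    gt_boxes : (G, 4) xyxy ground truth

    Returns ``(pos_mask, matched_gt, target_scores)``: a boolean positive
    mask over anchors, the GT index each positive serves, and the VFL target
    q (alignment normalized per GT to that GT's best IoU).
    """
    A = len(anchor_points)
    G = len(gt_boxes)
    pos_mask = np.zeros(A, dtype=bool)
    matched = np.full(A, -1, dtype=np.int64)
    q = np.zeros(A, dtype=np.float64)
    if G == 0:
        return pos_mask, matched, q
    t = alignment_metric(scores[:, None], ious, alpha, beta)  # (A, G)
    inside = (
        (anchor_points[:, 0:1] > gt_boxes[None, :, 0])
        & (anchor_points[:, 0:1] < gt_boxes[None, :, 2])
        & (anchor_points[:, 1:2] > gt_boxes[None, :, 1])
        & (anchor_points[:, 1:2] < gt_boxes[None, :, 3])
    )  # (A, G)
    cand_t = np.where(inside, t, -1.0)
    chosen = np.zeros((A, G), dtype=bool)
    for g in range(G):
        order = np.lexsort((np.arange(A), -ious[:, g], -cand_t[:, g]))
        picked = [a for a in order[:topk] if cand_t[a, g] >= 0]
        if not picked:
            import warnings

            warnings.warn(f"ground-truth box {g} has no candidate anchors; skipped")
            continue
        chosen[picked, g] = True
    any_pos = chosen.any(axis=1)
    # an anchor claimed by several GTs serves the one it overlaps most
    best_g = np.where(chosen, ious, -np.inf).argmax(axis=1)
    pos_mask[any_pos] = True
    matched[any_pos] = best_g[any_pos]
    # normalize alignment per GT to that GT's best IoU among its positives
    for g in range(G):
        sel = pos_mask & (matched == g)
        if not sel.any():
            continue
        tg = t[sel, g]
        q[sel] = tg / (tg.max() + _EPS) * ious[sel, g].max()
    return pos_mask, matched, q


def _vfl_tensor(logits: Tensor, q: np.ndarray, cfg: LossConfig) -> Tensor:
    p = logits.sigmoid().clip(_EPS, 1 - _EPS)
    qt = Tensor(q.astype(np.float32))
    pos_w = Tensor((q > 0).astype(np.float32))
    neg_w = Tensor((q == 0).astype(np.float32))
    log_p = p.log()
    log_1p = (Tensor(np.float32(1.0)) - p).log()
    pos = (qt * (qt * log_p + (1.0 - qt) * log_1p)) * pos_w * -1.0
    neg = (p**cfg.vfl_gamma * log_1p) * neg_w * (-cfg.vfl_alpha)
    return pos + neg


def detection_loss(raw_maps, targets, reg_max: int, nc: int, strides=(8, 16, 32),
                   cfg: LossConfig | None = None):
    """Composite loss over a batch of head outputs.

    ``raw_maps``: list of per-scale Tensors (N, 4*reg_max+nc, H, W);
    ``targets``: per-image arrays of xyxy GT boxes in input pixels.
    Returns ``(total, parts)`` with parts a dict of float components.
    """
    from .nn import concat

    cfg = cfg or LossConfig()
    n = raw_maps[0].shape[0]
    nreg = 4 * reg_max
    feats, centers, stride_v = [], [], []
    for m, s in zip(raw_maps, strides):
        _, c, h, w = m.shape
        feats.append(m.reshape(n, c, h * w).transpose(0, 2, 1))
        yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        centers.append(
            np.stack([(xx.ravel() + 0.5) * s, (yy.ravel() + 0.5) * s], axis=1)
        )
        stride_v.append(np.full(h * w, s, dtype=np.float32))
    feat = concat(feats, axis=1)  # (N, A, nreg+nc)
    centers = np.concatenate(centers, 0).astype(np.float32)
    stride_v = np.concatenate(stride_v, 0)
    A = centers.shape[0]

    reg_logits = feat[:, :, :nreg].reshape(n, A, 4, reg_max)
    cls_logits = feat[:, :, nreg:]
    proj = Tensor(np.arange(reg_max, dtype=np.float32))
    dist = reg_logits.softmax(axis=-1) @ proj  # (N, A, 4) grid units
    dist_px = dist * Tensor(stride_v[None, :, None])
    boxes = nn_boxes(dist_px, centers)  # (N, A, 4) xyxy Tensor

    box_terms, dfl_terms = [], []
    cls_losses = []
    total_q = 0.0
    n_pos_total = 0
    for i in range(n):
        gt = np.asarray(targets[i], dtype=np.float32).reshape(-1, 4)
        pred_b = boxes.data[i]
        scores_np = 1.0 / (1.0 + np.exp(-cls_logits.data[i, :, 0]))
        ious = _iou_matrix(pred_b, gt) if len(gt) else np.zeros((A, 0))
        pos, matched, q = task_aligned_assign(
            scores_np, ious, centers, gt,
            alpha=cfg.assigner_alpha, beta=cfg.assigner_beta, topk=cfg.assigner_topk,
        )
        cls_losses.append(_vfl_tensor(cls_logits[i, :, 0], q, cfg).sum())
        total_q += q.sum()
        idx = np.flatnonzero(pos)
        n_pos_total += len(idx)
        if len(idx) == 0:
            continue
        gt_sel = gt[matched[idx]]
        ciou_val, _ = _ciou_terms(boxes[i][idx], Tensor(gt_sel))
        w = Tensor((q[idx] / max(q[idx].sum(), _EPS)).astype(np.float32))
        box_terms.append(((1.0 - ciou_val) * w).sum())
        # DFL on the four side distances, in grid units
        tgt_d = np.stack(
            [
                centers[idx, 0] - gt_sel[:, 0],
                centers[idx, 1] - gt_sel[:, 1],
                gt_sel[:, 2] - centers[idx, 0],
                gt_sel[:, 3] - centers[idx, 1],
            ],
            axis=1,
        ) / stride_v[idx, None]
        tgt_d = np.clip(tgt_d, 0, reg_max - 1 - 0.01)
        lo = np.floor(tgt_d)
        wl = Tensor((lo + 1 - tgt_d).astype(np.float32))
        wr = Tensor((tgt_d - lo).astype(np.float32))
        probs = reg_logits[i][idx].softmax(axis=-1).clip(_EPS, 1.0)
        ii, jj = np.meshgrid(np.arange(len(idx)), np.arange(4), indexing="ij")
        p_lo = probs[ii, jj, lo.astype(np.int64)]
        p_hi = probs[ii, jj, np.minimum(lo + 1, reg_max - 1).astype(np.int64)]
        dfl = -(wl * p_lo.log() + wr * p_hi.log())
        dfl_terms.append((dfl.mean(axis=1) * w).sum())

    norm = max(total_q, 1.0)
    cls_loss = sum(cls_losses[1:], cls_losses[0]) * (1.0 / norm)
    if box_terms:
        box_loss = sum(box_terms[1:], box_terms[0]) * (1.0 / n)
        dfl_loss_t = sum(dfl_terms[1:], dfl_terms[0]) * (1.0 / n)
    else:
        box_loss = Tensor(np.float32(0.0))
        dfl_loss_t = Tensor(np.float32(0.0))
    total = cfg.box_gain * box_loss + cfg.cls_gain * cls_loss + cfg.dfl_gain * dfl_loss_t
    parts = {
        "box": float(box_loss.data),
        "cls": float(cls_loss.data),
        "dfl": float(dfl_loss_t.data),
        "n_pos": n_pos_total,
    }
    return total, parts


def nn_boxes(dist_px: Tensor, centers: np.ndarray) -> Tensor:
    """(l, t, r, b) distances + anchor centers -> xyxy boxes (Tensor)."""
    from .nn import stack

    cx = Tensor(centers[None, :, 0])
    cy = Tensor(centers[None, :, 1])
    return stack(
        [
            cx - dist_px[:, :, 0],
            cy - dist_px[:, :, 1],
            cx + dist_px[:, :, 2],
            cy + dist_px[:, :, 3],
        ],
        axis=2,
    )


def _iou_matrix(boxes1: np.ndarray, boxes2: np.ndarray) -> np.ndarray:
    from .evalmetrics import box_iou

    return box_iou(boxes1, boxes2)
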