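"""Detection loss: complete-IoU box term, distribution focal term on the
binned box sides, and binary cross-entropy on class scores.

Both head branches are supervised: the one-to-many branch through the
top-k task-aligned assignment, the one-to-one branch through the top-1
assignment.  Component weights default to box 7.5, dfl 1.5, cls 0.5
(conventional for this loss family; configurable)."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn import tensor as T
from .assign import AssignerConfig, assign_targets, make_anchors


@dataclass
class LossWeights:
    box: float = 7.5
    dfl: float = 1.5
    cls: float = 0.5


def ciou_loss(pred: T.Tensor, target: np.ndarray,
              weights: np.ndarray | None = None) -> T.Tensor:
    """Weighted mean (1 - CIoU) over (n, 4) cxcywh boxes.

    `target` is constant; `weights` (n,) are constant per-box weights
    normalized by their sum (uniform when omitted)."""
    t = np.asarray(target, dtype=np.float32)
    eps = 1e-7
    px1 = pred[:, 0] - pred[:, 2] * 0.5
    py1 = pred[:, 1] - pred[:, 3] * 0.5
    px2 = pred[:, 0] + pred[:, 2] * 0.5
    py2 = pred[:, 1] + pred[:, 3] * 0.5
    tx1, ty1 = t[:, 0] - t[:, 2] / 2, t[:, 1] - t[:, 3] / 2
    tx2, ty2 = t[:, 0] + t[:, 2] / 2, t[:, 1] + t[:, 3] / 2
    iw = T.clip(T.minimum(px2, tx2) - T.maximum(px1, tx1), 0.0, None)
    ih = T.clip(T.minimum(py2, ty2) - T.maximum(py1, ty1), 0.0, None)
    inter = iw * ih
    union = pred[:, 2] * pred[:, 3] + (t[:, 2] * t[:, 3]) - inter
    iou = inter / (union + eps)
    # enclosing box diagonal and center distance
    cw = T.maximum(px2, tx2) - T.minimum(px1, tx1)
    ch = T.maximum(py2, ty2) - T.minimum(py1, ty1)
    c2 = cw * cw + ch * ch + eps
    rho2 = ((pred[:, 0] - t[:, 0]) * (pred[:, 0] - t[:, 0])
            + (pred[:, 1] - t[:, 1]) * (pred[:, 1] - t[:, 1]))
    # aspect-ratio consistency
    v = T.arctan(T.astensor(t[:, 2] / np.maximum(t[:, 3], eps))) \
        - T.arctan(pred[:, 2] / (pred[:, 3] + eps))
    v = (4.0 / math.pi ** 2) * v * v
    alpha = v.detach() / T.clip((1.0 - iou).detach() + v.detach(), eps, None)
    ciou = iou - rho2 / c2 - T.astensor(alpha.data) * v
    one_minus = 1.0 - ciou
    if weights is None:
        return T.tmean(one_minus)
    w = np.asarray(weights, dtype=np.float32)
    return T.tsum(T.mul(one_minus, w / max(float(w.sum()), 1e-9)))


def dfl_loss(pred_dist_logits: T.Tensor, target_dist: np.ndarray,
             reg_max: int, weights: np.ndarray | None = None) -> T.Tensor:
    """Interpolated cross-entropy of binned side distances.

    pred_dist_logits: (n, 4, reg_max); target_dist: (n, 4) distances in
    stride units, clipped into [0, reg_max - 1]; optional per-box
    weights normalized by their sum."""
    t = np.clip(np.asarray(target_dist, dtype=np.float32), 0,
                reg_max - 1 - 1e-3)
    tl = np.floor(t).astype(int)
    tr = tl + 1
    wl = tr - t
    wr = t - tl
    logp = T.log_softmax(pred_dist_logits, axis=2)
    ll = T.gather(logp, tl[:, :, None], axis=2)
    lr = T.gather(logp, np.minimum(tr, reg_max - 1)[:, :, None], axis=2)
    loss = -(T.mul(ll, wl[:, :, None]) + T.mul(lr, wr[:, :, None]))
    per_box = T.tmean(T.reshape(loss, (loss.shape[0], -1)), axis=1)
    if weights is None:
        return T.tmean(per_box)
    w = np.asarray(weights, dtype=np.float32)
    return T.tsum(T.mul(per_box, w / max(float(w.sum()), 1e-9)))


def _flatten_levels(outputs: list, reg_max: int):
    """Per-level (cls, reg) tensors -> (N, cells, nc) and (N, cells, 4, reg_max)."""
    cls_all, reg_all = [], []
    for cls, reg in outputs:
        n, nc, h, w = cls.shape
        cls_all.append(T.reshape(T.transpose(cls, (0, 2, 3, 1)),
                                 (n, h * w, nc)))
        r = T.reshape(reg, (n, 4, reg_max, h * w))
        reg_all.append(T.transpose(r, (0, 3, 1, 2)))
    return T.concat(cls_all, axis=1), T.concat(reg_all, axis=1)


def _decode_cells(reg_logits_np: np.ndarray, anchors: np.ndarray,
                  strides: np.ndarray, input_size: int) -> np.ndarray:
    """Decode flattened (cells, 4, reg_max) logits to normalized boxes."""
    z = reg_logits_np - reg_logits_np.max(axis=2, keepdims=True)
    e = np.exp(z)
    dist = (e / e.sum(axis=2, keepdims=True)
            * np.arange(reg_logits_np.shape[2])).sum(axis=2)
    dist = dist * strides[:, None] / input_size
    x1 = anchors[:, 0] - dist[:, 0]
    y1 = anchors[:, 1] - dist[:, 1]
    x2 = anchors[:, 0] + dist[:, 2]
    y2 = anchors[:, 1] + dist[:, 3]
    return np.stack([(x1 + x2) / 2, (y1 + y2) / 2,
                     np.maximum(x2 - x1, 1e-6),
                     np.maximum(y2 - y1, 1e-6)], axis=1).astype(np.float32)


def _branch_loss(cls_flat, reg_flat, targets, anchors, strides, input_size,
                 reg_max, acfg, one_to_one):
    """Loss of one head branch across the batch; returns Tensor terms."""
    n, cells, nc = cls_flat.shape
    cls_target = np.zeros((n, cells, nc), dtype=np.float32)
    box_terms, dfl_terms = [], []
    total_pos = 0
    total_weight = 0.0
    for i in range(n):
        gt = targets[i]
        scores = 1.0 / (1.0 + np.exp(-np.clip(cls_flat.data[i], -60, 60)))
        boxes = _decode_cells(reg_flat.data[i], anchors, strides, input_size)
        asn = assign_targets(scores, boxes, anchors, gt, acfg,
                             one_to_one=one_to_one,
                             strides=strides / input_size)
        pos = np.nonzero(asn.fg_mask)[0]
        total_pos += pos.size
        if pos.size == 0:
            continue
        w = np.maximum(asn.target_score[pos], 1e-4)
        total_weight += float(w.sum())
        cls_target[i, pos, asn.gt_class[pos]] = asn.target_score[pos]
        # box term on decoded positives (autograd path)
        reg_pos = reg_flat[i, pos]                       # (p, 4, reg_max)
        dist = T.tsum(T.mul(T.softmax(reg_pos, axis=2),
                            np.arange(reg_max, dtype=np.float32)), axis=2)
        sc = strides[pos, None] / input_size
        ax, ay = anchors[pos, 0], anchors[pos, 1]
        x1 = T.astensor(ax) - dist[:, 0] * sc[:, 0]
        y1 = T.astensor(ay) - dist[:, 1] * sc[:, 0]
        x2 = T.astensor(ax) + dist[:, 2] * sc[:, 0]
        y2 = T.astensor(ay) + dist[:, 3] * sc[:, 0]
        pred_boxes = T.concat([
            T.reshape((x1 + x2) * 0.5, (-1, 1)),
            T.reshape((y1 + y2) * 0.5, (-1, 1)),
            T.reshape(x2 - x1, (-1, 1)),
            T.reshape(y2 - y1, (-1, 1))], axis=1)
        gt_boxes = asn.gt_box[pos]
        # weighted sum here; normalized by the batch weight total below
        box_terms.append(ciou_loss(pred_boxes, gt_boxes, weights=w)
                         * float(w.sum()))
        # dfl on target side distances in stride units
        gx1 = gt_boxes[:, 0] - gt_boxes[:, 2] / 2
        gy1 = gt_boxes[:, 1] - gt_boxes[:, 3] / 2
        gx2 = gt_boxes[:, 0] + gt_boxes[:, 2] / 2
        gy2 = gt_boxes[:, 1] + gt_boxes[:, 3] / 2
        su = input_size / strides[pos]
        tdist = np.stack([(anchors[pos, 0] - gx1) * su,
                          (anchors[pos, 1] - gy1) * su,
                          (gx2 - anchors[pos, 0]) * su,
                          (gy2 - anchors[pos, 1]) * su], axis=1)
        dfl_terms.append(dfl_loss(reg_pos, tdist, reg_max, weights=w)
                         * float(w.sum()))

    norm = max(total_weight, 1.0)
    cls_term = T.tsum(T.bce_with_logits(cls_flat, cls_target)) * (1.0 / norm)
    if box_terms:
        box_term = box_terms[0]
        for b in box_terms[1:]:
            box_term = box_term + b
        box_term = box_term * (1.0 / norm)
        dfl_term = dfl_terms[0]
        for d in dfl_terms[1:]:
            dfl_term = dfl_term + d
        dfl_term = dfl_term * (1.0 / norm)
    else:
        box_term = T.astensor(0.0)
        dfl_term = T.astensor(0.0)
    return box_term, dfl_term, cls_term, total_pos


def detection_loss(outputs: dict, targets: list, input_size: int,
                   reg_max: int = 16,
                   weights: LossWeights | None = None,
                   assigner: AssignerConfig | None = None):
    """Total loss over both branches for one batch.

    outputs: the model's forward dict; targets: per image list of
    (class_id, box cxcywh normalized).  Returns (total Tensor, dict of
    float components)."""
    weights = weights or LossWeights()
    acfg = assigner or AssignerConfig()
    strides_list = outputs["strides"]
    anchors, strides = make_anchors(strides_list, input_size)
    comps = {}
    total = None
    for branch, o2o in (("one2many", False), ("one2one", True)):
        cls_flat, reg_flat = _flatten_levels(outputs[branch], reg_max)
        box_t, dfl_t, cls_t, npos = _branch_loss(
            cls_flat, reg_flat, targets, anchors, strides, input_size,
            reg_max, acfg, o2o)
        branch_total = (box_t * weights.box + dfl_t * weights.dfl
                        + cls_t * weights.cls)
        comps[f"{branch}/box"] = float(box_t.data)
        comps[f"{branch}/dfl"] = float(dfl_t.data)
        comps[f"{branch}/cls"] = float(cls_t.data)
        comps[f"{branch}/num_pos"] = npos
        total = branch_total if total is None else total + branch_total
    comps["box"] = comps["one2many/box"]
    comps["dfl"] = comps["one2many/dfl"]
    comps["cls"] = comps["one2many/cls"]
    comps["total"] = float(total.data)
    return total, comps
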