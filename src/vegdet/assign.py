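"""Task-aligned target assignment.

Candidates for a ground-truth box are the cells whose anchor center
falls inside it; they are ranked by the alignment metric
``score**alpha * IoU**beta`` and the top-k become positives of the
one-to-many branch (the one-to-one branch takes the single best).  A
ground truth whose box contains no anchor center falls back to the
highest-IoU cell, so every ground truth with nonzero overlap receives
at least one candidate.  When two ground truths claim one cell, the
higher metric wins.  All ties break deterministically toward the lowest
flat cell index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import iou_cxcywh


@dataclass
class AssignerConfig:
    topk: int = 10
    alpha: float = 0.5
    beta: float = 6.0
    # candidate cells are those whose anchor center lies inside the box
    # OR within center_radius cell-strides of the box center; the radius
    # keeps targets for sub-cell boxes stable instead of hopping with
    # the predictions
    center_radius: float = 1.5


@dataclass
class Assignment:
    """Per-image assignment over the flattened cell list."""
    fg_mask: np.ndarray          # (cells,) bool
    gt_index: np.ndarray         # (cells,) int, -1 for background
    gt_class: np.ndarray         # (cells,) int
    gt_box: np.ndarray           # (cells, 4) normalized cxcywh
    metric: np.ndarray           # (cells,) alignment metric of the match
    target_score: np.ndarray     # (cells,) IoU-aware soft class target

    @property
    def num_positives(self) -> int:
        return int(self.fg_mask.sum())


def make_anchors(strides: list[int], input_size: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Flattened anchor centers (normalized xy) and per-cell strides."""
    centers, st = [], []
    for s in strides:
        n = input_size // s
        ys, xs = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        cx = (xs.ravel() + 0.5) * s / input_size
        cy = (ys.ravel() + 0.5) * s / input_size
        centers.append(np.stack([cx, cy], axis=1))
        st.append(np.full(n * n, s))
    return (np.concatenate(centers).astype(np.float32),
            np.concatenate(st).astype(np.float32))


def _topk_desc(values: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest values, ties toward the lowest index."""
    order = np.lexsort((np.arange(values.size), -values))
    return order[:k]


def assign_targets(pred_scores: np.ndarray, pred_boxes: np.ndarray,
                   anchors: np.ndarray, gt: list[tuple[int, np.ndarray]],
                   cfg: AssignerConfig | None = None,
                   one_to_one: bool = False,
                   strides: np.ndarray | None = None) -> Assignment:
    """Assign ground truths to cells for one image.

    pred_scores: (cells, nc) class probabilities; pred_boxes: (cells, 4)
    normalized cxcywh; anchors: (cells, 2) normalized centers;
    gt: list of (class_id, box); strides: per-cell strides normalized by
    the input size (enables the center-radius candidate rule)."""
    cfg = cfg or AssignerConfig()
    cells = pred_scores.shape[0]
    fg = np.zeros(cells, dtype=bool)
    gt_index = np.full(cells, -1, dtype=int)
    gt_class = np.zeros(cells, dtype=int)
    gt_box = np.zeros((cells, 4), dtype=np.float32)
    best_metric = np.zeros(cells, dtype=np.float32)
    cell_iou = np.zeros(cells, dtype=np.float32)
    target_score = np.zeros(cells, dtype=np.float32)
    if not gt:
        return Assignment(fg, gt_index, gt_class, gt_box, best_metric,
                          target_score)

    k = 1 if one_to_one else cfg.topk
    for gi, (cid, box) in enumerate(gt):
        box = np.asarray(box, dtype=np.float32)
        x1, y1 = box[0] - box[2] / 2, box[1] - box[3] / 2
        x2, y2 = box[0] + box[2] / 2, box[1] + box[3] / 2
        inside = ((anchors[:, 0] >= x1) & (anchors[:, 0] <= x2) &
                  (anchors[:, 1] >= y1) & (anchors[:, 1] <= y2))
        if not inside.any() and strides is not None:
            # sub-cell box: fall back to center sampling so its targets
            # stay stable instead of hopping with the predictions
            inside = (np.abs(anchors[:, 0] - box[0])
                      <= cfg.center_radius * strides) & \
                     (np.abs(anchors[:, 1] - box[1])
                      <= cfg.center_radius * strides)
        ious = iou_cxcywh(pred_boxes, box[None])
        if not inside.any():
            # final fallback: the anchor nearest the box center
            d = np.abs(anchors[:, 0] - box[0]) + np.abs(anchors[:, 1] - box[1])
            cand = np.array([_topk_desc(-d, 1)[0]])
        else:
            idx = np.nonzero(inside)[0]
            metric = (pred_scores[idx, cid] ** cfg.alpha
                      * ious[idx] ** cfg.beta)
            cand = idx[_topk_desc(metric, k)]
        for c in cand:
            m = float(pred_scores[c, cid] ** cfg.alpha
                      * max(ious[c], 1e-9) ** cfg.beta)
            if not fg[c] or m > best_metric[c]:
                fg[c] = True
                gt_index[c] = gi
                gt_class[c] = cid
                gt_box[c] = box
                best_metric[c] = m
                cell_iou[c] = max(float(ious[c]), 0.0)

    # IoU-aware soft class targets: per ground truth, scale the metric so
    # its best cell targets that cell's IoU (task-aligned convention)
    for gi in range(len(gt)):
        cells_gi = np.nonzero(fg & (gt_index == gi))[0]
        if cells_gi.size == 0:
            continue
        mmax = best_metric[cells_gi].max()
        imax = cell_iou[cells_gi].max()
        if mmax > 0:
            target_score[cells_gi] = (best_metric[cells_gi] / mmax) * imax
        else:
            target_score[cells_gi] = imax
    return Assignment(fg, gt_index, gt_class, gt_box, best_metric,
                      target_score)
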