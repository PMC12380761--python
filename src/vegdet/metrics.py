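"""Detection evaluation: AP/mAP, PR curves, confusion matrix.

Matching follows the COCO-style protocol: per class, detections are
taken in descending score order and greedily matched to the unmatched
ground-truth box of highest IoU above the threshold, each ground truth
matched at most once.  AP integrates the 101-point interpolated
precision-recall curve; mAP@0.5:0.95 averages IoU thresholds
0.50:0.05:0.95.  Reported precision/recall are taken at the score
threshold maximizing F1.  Classes without ground truth are excluded
from macro means and listed in the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class Detection:
    class_id: int
    score: float
    box: tuple[float, float, float, float]   # normalized (cx, cy, w, h)


def _asdet(d) -> Detection:
    if isinstance(d, Detection):
        return d
    if isinstance(d, dict):
        return Detection(int(d["class_id"]), float(d["score"]),
                         tuple(d["box"]))
    cid, score, box = d
    return Detection(int(cid), float(score), tuple(box))


def iou_cxcywh(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of (..., 4) cxcywh boxes; broadcasting applies."""
    ax1, ay1 = a[..., 0] - a[..., 2] / 2, a[..., 1] - a[..., 3] / 2
    ax2, ay2 = a[..., 0] + a[..., 2] / 2, a[..., 1] + a[..., 3] / 2
    bx1, by1 = b[..., 0] - b[..., 2] / 2, b[..., 1] - b[..., 3] / 2
    bx2, by2 = b[..., 0] + b[..., 2] / 2, b[..., 1] + b[..., 3] / 2
    iw = np.clip(np.minimum(ax2, bx2) - np.maximum(ax1, bx1), 0, None)
    ih = np.clip(np.minimum(ay2, by2) - np.maximum(ay1, by1), 0, None)
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / np.maximum(union, 1e-12)


def interpolated_ap(recall: np.ndarray, precision: np.ndarray,
                    points: int = 101) -> float:
    """Area under the right-envelope PR curve sampled at `points` recalls."""
    if recall.size == 0:
        return 0.0
    grid = np.linspace(0, 1, points)
    # precision envelope: max precision at recall >= r
    order = np.argsort(recall)
    r, p = recall[order], precision[order]
    env = np.maximum.accumulate(p[::-1])[::-1]
    idx = np.searchsorted(r, grid, side="left")
    vals = np.where(idx < r.size, env[np.minimum(idx, r.size - 1)], 0.0)
    return float(vals.mean())


def _match_class(dets, gts, iou_t: float):
    """Greedy matching for one class across images.

    dets: list of (image_id, score, box); gts: dict image_id -> [boxes].
    Returns (tp, fp) arrays aligned with score-sorted detections."""
    order = sorted(range(len(dets)),
                   key=lambda i: (-dets[i][1], dets[i][0], i))
    matched: dict[tuple[int, int], bool] = {}
    tp = np.zeros(len(dets))
    fp = np.zeros(len(dets))
    for rank, i in enumerate(order):
        img, _, box = dets[i]
        cands = gts.get(img, [])
        best, best_iou = -1, iou_t
        for gi, gbox in enumerate(cands):
            if matched.get((img, gi)):
                continue
            v = float(iou_cxcywh(np.asarray(box), np.asarray(gbox)))
            if v >= best_iou:
                best, best_iou = gi, v
        if best >= 0:
            matched[(img, best)] = True
            tp[rank] = 1
        else:
            fp[rank] = 1
    scores = np.array([dets[i][1] for i in order])
    return tp, fp, scores


@dataclass
class EvalReport:
    class_names: list[str]
    precision: dict[int, float]       # percent, at max-F1 threshold (IoU .5)
    recall: dict[int, float]
    ap50: dict[int, float]
    ap5095: dict[int, float]
    map50: float
    map5095: float
    pr_curves: dict[int, list[tuple[float, float]]]
    confusion: np.ndarray             # (nc+1, nc+1), rows = true class
    excluded_classes: list[int]       # no ground truth -> not in macro means

    @property
    def macro_precision(self) -> float:
        vals = [v for k, v in self.precision.items()
                if k not in self.excluded_classes]
        return float(np.mean(vals)) if vals else 0.0

    @property
    def macro_recall(self) -> float:
        vals = [v for k, v in self.recall.items()
                if k not in self.excluded_classes]
        return float(np.mean(vals)) if vals else 0.0

    def to_dict(self) -> dict:
        return {
            "map50": self.map50, "map5095": self.map5095,
            "precision": self.macro_precision, "recall": self.macro_recall,
            "per_class": {
                self.class_names[c] if c < len(self.class_names) else str(c): {
                    "precision": self.precision.get(c),
                    "recall": self.recall.get(c),
                    "ap50": self.ap50.get(c),
                    "ap5095": self.ap5095.get(c),
                } for c in sorted(self.ap50)},
            "excluded_classes": self.excluded_classes,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def save_confusion_csv(self, path) -> None:
        names = list(self.class_names) + ["background"]
        lines = ["true\\pred," + ",".join(names)]
        for i, row in enumerate(self.confusion):
            lines.append(names[i] + "," + ",".join(str(int(v)) for v in row))
        Path(path).write_text("\n".join(lines) + "\n")

    def save_pr_csv(self, path) -> None:
        lines = ["class,recall,precision"]
        for c, pts in self.pr_curves.items():
            for r, p in pts:
                lines.append(f"{self.class_names[c]},{r:.4f},{p:.4f}")
        Path(path).write_text("\n".join(lines) + "\n")


def evaluate(detections: list[list], ground_truth: list[list],
             num_classes: int,
             iou_thresholds: tuple[float, ...] | None = None,
             class_names: list[str] | None = None,
             conf_score_thresh: float = 0.25) -> EvalReport:
    """Score detections against ground truth.

    `detections[i]` — Detection/dict/(cid, score, box) for image i;
    `ground_truth[i]` — (cid, box) or data.Box for image i.
    """
    if iou_thresholds is None:
        iou_thresholds = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))
    names = class_names or [str(c) for c in range(num_classes)]
    dets_by_class: dict[int, list] = {c: [] for c in range(num_classes)}
    gts_by_class: dict[int, dict[int, list]] = {c: {} for c in range(num_classes)}
    gt_counts = np.zeros(num_classes, dtype=int)
    for img, dd in enumerate(detections):
        for d in dd:
            d = _asdet(d)
            dets_by_class[d.class_id].append((img, d.score, d.box))
    for img, gg in enumerate(ground_truth):
        for g in gg:
            if hasattr(g, "class_id"):
                cid, box = g.class_id, (g.cx, g.cy, g.w, g.h)
            else:
                cid, box = int(g[0]), tuple(g[1])
            gts_by_class[cid].setdefault(img, []).append(box)
            gt_counts[cid] += 1

    ap50, ap5095, precision, recall = {}, {}, {}, {}
    pr_curves = {}
    excluded = [c for c in range(num_classes) if gt_counts[c] == 0]
    for c in range(num_classes):
        if c in excluded:
            continue
        aps = []
        for t in iou_thresholds:
            tp, fp, scores = _match_class(dets_by_class[c], gts_by_class[c], t)
            ctp, cfp = tp.cumsum(), fp.cumsum()
            # emit PR points only where the score strictly drops, so AP is
            # invariant to detection ordering within equal scores
            if scores.size:
                keep = np.append(scores[:-1] != scores[1:], True)
                ctp, cfp = ctp[keep], cfp[keep]
            rec = ctp / gt_counts[c]
            prec = ctp / np.maximum(ctp + cfp, 1e-12)
            ap = interpolated_ap(rec, prec)
            aps.append(ap)
            if abs(t - 0.5) < 1e-9:
                ap50[c] = 100.0 * ap
                pr_curves[c] = list(zip(rec.tolist(), prec.tolist()))
                if rec.size:
                    f1 = 2 * prec * rec / np.maximum(prec + rec, 1e-12)
                    i = int(f1.argmax())
                    precision[c] = 100.0 * float(prec[i])
                    recall[c] = 100.0 * float(rec[i])
                else:
                    precision[c] = 0.0
                    recall[c] = 0.0
        ap5095[c] = 100.0 * float(np.mean(aps))

    valid = [c for c in range(num_classes) if c not in excluded]
    map50 = float(np.mean([ap50[c] for c in valid])) if valid else 0.0
    map5095 = float(np.mean([ap5095[c] for c in valid])) if valid else 0.0
    confusion = _confusion_matrix(detections, ground_truth, num_classes,
                                  conf_score_thresh)
    return EvalReport(names, precision, recall, ap50, ap5095, map50,
                      map5095, pr_curves, confusion, excluded)


def _confusion_matrix(detections, ground_truth, nc: int,
                      score_thresh: float, iou_t: float = 0.5) -> np.ndarray:
    """(nc+1)x(nc+1); rows true class, cols predicted; last index is
    background (unmatched)."""
    m = np.zeros((nc + 1, nc + 1), dtype=int)
    for img in range(len(ground_truth)):
        dd = [_asdet(d) for d in (detections[img] if img < len(detections)
                                  else [])]
        dd = [d for d in dd if d.score >= score_thresh]
        dd.sort(key=lambda d: -d.score)
        gg = []
        for g in ground_truth[img]:
            if hasattr(g, "class_id"):
                gg.append((g.class_id, np.array((g.cx, g.cy, g.w, g.h))))
            else:
                gg.append((int(g[0]), np.asarray(g[1])))
        taken = [False] * len(gg)
        for d in dd:
            best, best_iou = -1, iou_t
            for gi, (gcid, gbox) in enumerate(gg):
                if taken[gi]:
                    continue
                v = float(iou_cxcywh(np.asarray(d.box), gbox))
                if v >= best_iou:
                    best, best_iou = gi, v
            if best >= 0:
                taken[best] = True
                m[gg[best][0], d.class_id] += 1
            else:
                m[nc, d.class_id] += 1          # background false positive
        for gi, (gcid, _) in enumerate(gg):
            if not taken[gi]:
                m[gcid, nc] += 1                # missed ground truth
    return m
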