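"""Independent brute-force oracles shared by the test suite."""

import numpy as np


def _iou_plain(a, b):
    """Scalar IoU written independently (corner arithmetic with floats)."""
    ax1, ay1, ax2, ay2 = a[0] - a[2] / 2, a[1] - a[3] / 2, \
        a[0] + a[2] / 2, a[1] + a[3] / 2
    bx1, by1, bx2, by2 = b[0] - b[2] / 2, b[1] - b[3] / 2, \
        b[0] + b[2] / 2, b[1] + b[3] / 2
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / ((ax2 - ax1) * (ay2 - ay1)
                    + (bx2 - bx1) * (by2 - by1) - inter)


def brute_force_ap(dets, gts, iou_t=0.5):
    """Oracle: explicit greedy matching loops + definitional 101-point AP.

    dets: list of (img, score, box) one class; gts: {img: [boxes]}."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i][1], dets[i][0], i))
    n_gt = sum(len(v) for v in gts.values())
    if n_gt == 0:
        return None
    used = set()
    points = []      # (recall, precision) at each strict score drop
    tp = fp = 0
    for rank, i in enumerate(order):
        img, _, box = dets[i]
        best_gi, best_iou = None, iou_t
        for gi, gbox in enumerate(gts.get(img, [])):
            if (img, gi) in used:
                continue
            v = _iou_plain(box, gbox)
            if v >= best_iou:
                best_gi, best_iou = gi, v
        if best_gi is not None:
            used.add((img, best_gi))
            tp += 1
        else:
            fp += 1
        is_last = rank == len(order) - 1
        if is_last or dets[order[rank + 1]][1] != dets[i][1]:
            points.append((tp / n_gt, tp / (tp + fp)))
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        ps = [p for (rec, p) in points if rec >= r]
        ap += max(ps) if ps else 0.0
    return ap / 101
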