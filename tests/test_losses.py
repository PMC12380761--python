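"""Loss family: CIoU, distribution focal term, and the assembled
detection loss against a brute-force loop oracle on a tiny grid."""

import numpy as np
import pytest

from vegdet import nn
from vegdet.assign import AssignerConfig, assign_targets, make_anchors
from vegdet.losses import (LossWeights, _decode_cells, ciou_loss,
                           detection_loss, dfl_loss)
from vegdet.nn import tensor as T


class TestCIoU:
    def test_exact_match_is_zero(self):
        box = np.array([[0.5, 0.5, 0.2, 0.3]], np.float32)
        pred = T.Tensor(box)
        assert float(ciou_loss(pred, box).data) == pytest.approx(0.0,
                                                                 abs=1e-5)

    def test_positive_and_bounded(self, rng):
        pred = T.Tensor(rng.uniform(0.2, 0.8, (10, 4)).astype(np.float32))
        tgt = rng.uniform(0.2, 0.8, (10, 4)).astype(np.float32)
        v = float(ciou_loss(pred, tgt).data)
        assert 0 <= v < 3      # 1 - ciou in (0, 2+aspect term)

    def test_gradient_pulls_toward_target(self):
        pred = nn.Parameter(np.array([[0.3, 0.5, 0.2, 0.2]]))
        tgt = np.array([[0.6, 0.5, 0.2, 0.2]], np.float32)
        ciou_loss(pred, tgt).backward()
        # moving cx toward 0.6 lowers the loss -> negative gradient on cx
        assert pred.grad[0, 0] < 0


class TestDFL:
    def test_bin_center_target_is_one_hot_cross_entropy(self, rng):
        logits = nn.Parameter(rng.normal(size=(3, 4, 8)))
        t = np.array([[2.0, 5.0, 1.0, 0.0],
                      [3.0, 3.0, 3.0, 3.0],
                      [6.0, 0.0, 2.0, 4.0]], np.float32)
        loss = dfl_loss(logits, t, reg_max=8)
        z = logits.data - logits.data.max(axis=2, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=2, keepdims=True))
        ref = -np.take_along_axis(logp, t.astype(int)[:, :, None],
                                  axis=2).mean()
        assert float(loss.data) == pytest.approx(ref, rel=1e-4)

    def test_interpolation_weights(self, rng):
        # target 2.25 -> bins 2 and 3 with weights .75/.25
        logits = T.Tensor(rng.normal(size=(1, 1, 8)).astype(np.float32))
        t = np.array([[2.25]], np.float32)
        loss = dfl_loss(logits, t, reg_max=8)
        z = logits.data - logits.data.max()
        logp = (z - np.log(np.exp(z).sum()))[0, 0]
        ref = -(0.75 * logp[2] + 0.25 * logp[3])
        assert float(loss.data) == pytest.approx(ref, rel=1e-4)


def brute_force_branch_loss(cls_logits, reg_logits, gt, anchors, strides,
                            input_size, reg_max, acfg):
    """Explicit-loop oracle for one image, one branch: recompute the
    assignment, then each loss term cell by cell with plain floats."""

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    scores = sig(cls_logits)
    boxes = _decode_cells(reg_logits, anchors, strides, input_size)
    asn = assign_targets(scores, boxes, anchors, gt, acfg,
                         strides=strides / input_size)
    pos = np.nonzero(asn.fg_mask)[0]
    w = np.maximum(asn.target_score[pos], 1e-4)
    # cls: elementwise BCE with soft targets, summed, / sum of weights
    tmat = np.zeros_like(cls_logits)
    for p, c, s in zip(pos, asn.gt_class[pos], asn.target_score[pos]):
        tmat[p, c] = s
    eps = 1e-12
    bce = -(tmat * np.log(scores + eps)
            + (1 - tmat) * np.log(1 - scores + eps)).sum()
    norm = max(w.sum(), 1.0)
    cls_term = bce / norm
    # box: weighted 1-CIoU via an independent scalar implementation
    import math

    def ciou_scalar(p, t):
        px1, py1, px2, py2 = p[0] - p[2] / 2, p[1] - p[3] / 2, \
            p[0] + p[2] / 2, p[1] + p[3] / 2
        tx1, ty1, tx2, ty2 = t[0] - t[2] / 2, t[1] - t[3] / 2, \
            t[0] + t[2] / 2, t[1] + t[3] / 2
        iw = max(min(px2, tx2) - max(px1, tx1), 0)
        ih = max(min(py2, ty2) - max(py1, ty1), 0)
        inter = iw * ih
        union = p[2] * p[3] + t[2] * t[3] - inter
        iou = inter / (union + 1e-7)
        cw = max(px2, tx2) - min(px1, tx1)
        ch = max(py2, ty2) - min(py1, ty1)
        c2 = cw * cw + ch * ch + 1e-7
        rho2 = (p[0] - t[0]) ** 2 + (p[1] - t[1]) ** 2
        v = 4 / math.pi ** 2 * (math.atan(t[2] / max(t[3], 1e-7))
                                - math.atan(p[2] / (p[3] + 1e-7))) ** 2
        alpha = v / max(1 - iou + v, 1e-7)
        return 1 - (iou - rho2 / c2 - alpha * v)

    box_sum = 0.0
    dfl_sum = 0.0
    for p, wi in zip(pos, w):
        box_sum += wi * ciou_scalar(boxes[p], asn.gt_box[p]) / w.sum()
        gb = asn.gt_box[p]
        su = input_size / strides[p]
        td = [(anchors[p, 0] - (gb[0] - gb[2] / 2)) * su,
              (anchors[p, 1] - (gb[1] - gb[3] / 2)) * su,
              ((gb[0] + gb[2] / 2) - anchors[p, 0]) * su,
              ((gb[1] + gb[3] / 2) - anchors[p, 1]) * su]
        side = 0.0
        for k in range(4):
            t = min(max(td[k], 0), reg_max - 1 - 1e-3)
            tl, tr = int(np.floor(t)), int(np.floor(t)) + 1
            wl, wr = tr - t, t - tl
            z = reg_logits[p, k] - reg_logits[p, k].max()
            logp = z - np.log(np.exp(z).sum())
            side += -(wl * logp[tl] + wr * logp[min(tr, reg_max - 1)])
        dfl_sum += wi * (side / 4) / w.sum()
    box_term = box_sum * w.sum() / norm
    dfl_term = dfl_sum * w.sum() / norm
    return box_term, dfl_term, cls_term


class TestDetectionLoss:
    def _tiny_outputs(self, rng, nc=2, reg_max=8, grid=2):
        cells = grid * grid
        cls = rng.normal(size=(1, nc, grid, grid)).astype(np.float32)
        reg = rng.normal(size=(1, 4 * reg_max, grid, grid)).astype(np.float32)
        out = {"one2many": [(T.Tensor(cls), T.Tensor(reg))],
               "one2one": [(T.Tensor(cls), T.Tensor(reg))],
               "strides": [8]}
        return out, cls, reg

    def test_matches_loop_oracle_on_2x2_grid(self, rng):
        reg_max = 8
        input_size = 16
        acfg = AssignerConfig(topk=2)
        for _ in range(5):
            out, cls, reg = self._tiny_outputs(rng, reg_max=reg_max)
            gt = [(0, np.array([0.4, 0.45, 0.3, 0.35], np.float32)),
                  (1, np.array([0.7, 0.7, 0.2, 0.2], np.float32))]
            total, comps = detection_loss(out, [gt], input_size,
                                          reg_max=reg_max,
                                          assigner=acfg)
            anchors, strides = make_anchors([8], input_size)
            cls_flat = cls.reshape(2, 4).T
            reg_flat = reg.reshape(4, reg_max, 4).transpose(2, 0, 1)
            ob, od, oc = brute_force_branch_loss(
                cls_flat, reg_flat, gt, anchors, strides, input_size,
                reg_max, acfg)
            assert comps["one2many/box"] == pytest.approx(ob, rel=1e-3)
            assert comps["one2many/dfl"] == pytest.approx(od, rel=1e-3)
            assert comps["one2many/cls"] == pytest.approx(oc, rel=1e-3)

    def test_components_nonnegative_finite(self, rng):
        out, _, _ = self._tiny_outputs(rng)
        gt = [(0, np.array([0.5, 0.5, 0.4, 0.4], np.float32))]
        total, comps = detection_loss(out, [gt], 16, reg_max=8)
        for k in ("box", "dfl", "cls"):
            assert comps[k] >= 0 and np.isfinite(comps[k])
        assert np.isfinite(float(total.data))

    def test_no_ground_truth_trains_pure_background(self, rng):
        out, _, _ = self._tiny_outputs(rng)
        total, comps = detection_loss(out, [[]], 16, reg_max=8)
        assert comps["box"] == 0.0 and comps["dfl"] == 0.0
        assert comps["cls"] > 0.0

    def test_weights_scale_components(self, rng):
        out, _, _ = self._tiny_outputs(rng)
        gt = [(0, np.array([0.5, 0.5, 0.4, 0.4], np.float32))]
        _, c1 = detection_loss(out, [gt], 16, reg_max=8,
                               weights=LossWeights(box=1, dfl=0, cls=0))
        out2, _, _ = self._tiny_outputs(rng)
        assert c1["total"] == pytest.approx(
            c1["one2many/box"] + c1["one2one/box"], rel=1e-5)
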