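"""Detector assembly: backbone, neck variants, MFLayer route, dual heads.

The family follows the anchor-free single-stage design: a staged
backbone emitting a feature pyramid (P2-P5), a fusion neck over P3-P5,
and per-level decoupled heads predicting class scores and binned box
regression.  Two parallel head sets are trained — a one-to-many set
supervised densely and a one-to-one set enabling NMS-free inference.

Three architecture switches define the ablation grid:

* ``use_adeconv`` — every spatial-reduction step in the backbone becomes
  a space-to-depth + ghost-convolution unit (no strided convolutions);
* ``use_mflayer`` — a stride-4 route fusing backbone P2 with the neck's
  P5-path output after three 2x upsamplings, feeding an added
  small-target head (head strides {4, 8, 16, 32});
* ``use_idfnet`` — the plain PAFPN neck is replaced by a repeated
  weighted bidirectional fusion over P3-P5 with AAFS attention gates at
  every fusion node and extra backbone-to-neck skip edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import tensor as T
from .blocks import ADEConv, ADEConvConfig, AAFS, AAFSConfig
from .topology import WidthProfile, resolve_profile, scaled


# ---------------------------------------------------------------------------
# config

@dataclass
class ModelConfig:
    num_classes: int = 15
    input_size: int = 640
    use_adeconv: bool = False
    use_mflayer: bool = False
    use_idfnet: bool = False
    neck_repeats: int = 3
    width_scale: float = 1.0
    profile: WidthProfile | None = None

    def __post_init__(self):
        if self.input_size % 32:
            raise ValueError(
                f"input_size must be divisible by 32, got {self.input_size}")
        if self.profile is None:
            self.profile = scaled(
                resolve_profile(self.use_adeconv, self.use_mflayer,
                                self.use_idfnet), self.width_scale)

    @property
    def head_strides(self) -> tuple[int, ...]:
        return (4, 8, 16, 32) if self.use_mflayer else (8, 16, 32)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        prof = d.pop("profile", None)
        cfg = cls(**d)
        if prof is not None:
            cfg.profile = WidthProfile(**prof)
        return cfg

    def to_dict(self) -> dict:
        from dataclasses import asdict
        d = asdict(self)
        return d


# ---------------------------------------------------------------------------
# shared building blocks

class Bottleneck(nn.Module):
    """Residual mixer; the `lite` form uses depthwise 3x3 + pointwise
    convolutions (the compact-block style of the n-scale baseline's
    late stages) instead of two dense 3x3 convolutions."""

    def __init__(self, c: int, shortcut: bool = True, lite: bool = False):
        super().__init__()
        if lite:
            self.cv1 = nn.ConvBNAct(c, c, kernel=3, groups=c)
            self.cv2 = nn.Sequential(nn.ConvBNAct(c, c, kernel=1),
                                     nn.ConvBNAct(c, c, kernel=3, groups=c))
        else:
            self.cv1 = nn.ConvBNAct(c, c, kernel=3)
            self.cv2 = nn.ConvBNAct(c, c, kernel=3)
        self.shortcut = shortcut

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return T.add(x, y) if self.shortcut else y


class CSPStage(nn.Module):
    """Cross-stage partial block: split, run n bottlenecks on one half,
    concatenate every intermediate, 1x1 merge."""

    def __init__(self, cin: int, cout: int, n: int = 1, shortcut: bool = True,
                 lite: bool = False):
        super().__init__()
        self.half = cout // 2
        self.cv1 = nn.ConvBNAct(cin, 2 * self.half, kernel=1)
        self.blocks = nn.ModuleList(
            [Bottleneck(self.half, shortcut, lite) for _ in range(n)])
        self.cv2 = nn.ConvBNAct((2 + n) * self.half, cout, kernel=1)

    def forward(self, x):
        y = self.cv1(x)
        a = y[:, : self.half]
        b = y[:, self.half:]
        outs = [a, b]
        for blk in self.blocks:
            outs.append(blk(outs[-1]))
        return self.cv2(T.concat(outs, axis=1))


class SCDown(nn.Module):
    """Separable compact downsampling: 1x1 channel map + depthwise 3x3 stride 2."""

    def __init__(self, cin: int, cout: int):
        super().__init__()
        self.cv1 = nn.ConvBNAct(cin, cout, kernel=1)
        self.cv2 = nn.ConvBNAct(cout, cout, kernel=3, stride=2, groups=cout,
                                act="none")

    def forward(self, x):
        return self.cv2(self.cv1(x))


class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): three chained 5x5 max pools."""

    def __init__(self, c: int):
        super().__init__()
        self.cv1 = nn.ConvBNAct(c, c // 2, kernel=1)
        self.cv2 = nn.ConvBNAct(2 * c, c, kernel=1)
        self.pool = nn.MaxPool2d(5, 1, 2)

    def forward(self, x):
        y = self.cv1(x)
        p1 = self.pool(y)
        p2 = self.pool(p1)
        p3 = self.pool(p2)
        return self.cv2(T.concat([y, p1, p2, p3], axis=1))


class AttnBlock(nn.Module):
    """Final-stage attention block: half the channels pass through a
    channel-gate + depthwise 7x7 spatial mixing + pointwise feed-forward
    path, the other half is carried through; 1x1 merge."""

    def __init__(self, c: int):
        super().__init__()
        h = c // 2
        self.cv1 = nn.ConvBNAct(c, c, kernel=1)
        self.gate_fc = nn.Conv2d(h, h, kernel=1)
        self.spatial = nn.ConvBNAct(h, h, kernel=7, groups=h)
        self.ffn1 = nn.ConvBNAct(h, c, kernel=1)
        self.ffn2 = nn.ConvBNAct(c, h, kernel=1, act="none")
        self.cv2 = nn.ConvBNAct(c, c, kernel=1)
        self.half = h

    def forward(self, x):
        y = self.cv1(x)
        a = y[:, : self.half]
        b = y[:, self.half:]
        g = T.sigmoid(self.gate_fc(T.tmean(b, axis=(2, 3), keepdims=True)))
        b = self.spatial(T.mul(b, g))
        b = T.add(b, self.ffn2(self.ffn1(b)))
        return self.cv2(T.concat([a, b], axis=1))


def make_downsample(cin: int, cout: int, position: str, use_adeconv: bool,
                    cheap_groups: int | None) -> nn.Module:
    """One spatial-reduction step.  With ADEConv on, every position —
    including the ones the baseline serves with SCDown — becomes a
    space-to-depth + ghost unit and the graph contains no stride-2 conv."""
    if use_adeconv:
        return ADEConv(ADEConvConfig(cin, cout, scale=2,
                                     cheap_groups=cheap_groups))
    if position == "late":
        return SCDown(cin, cout)
    return nn.ConvBNAct(cin, cout, kernel=3, stride=2)


# ---------------------------------------------------------------------------
# backbone

class Backbone(nn.Module):
    """Staged backbone emitting {P2, P3, P4, P5}."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        p = cfg.profile
        c1, c2, c3, c4, c5 = p.chans
        d2, d3, d4, d5 = p.depths
        ade, g = cfg.use_adeconv, p.ade_cheap_groups
        l2, l3, l4, l5 = p.stage_lite
        self.stem = make_downsample(3, c1, "early", ade, g)
        self.down2 = make_downsample(c1, c2, "early", ade, g)
        self.stage2 = CSPStage(c2, c2, d2, lite=l2)
        self.down3 = make_downsample(c2, c3, "early", ade, g)
        self.stage3 = CSPStage(c3, c3, d3, lite=l3)
        self.down4 = make_downsample(c3, c4, "late", ade, g)
        self.stage4 = CSPStage(c4, c4, d4, lite=l4)
        self.down5 = make_downsample(c4, c5, "late", ade, g)
        self.stage5 = CSPStage(c5, c5, d5, lite=l5)
        self.sppf = SPPF(c5)
        self.attn = AttnBlock(c5)

    def forward(self, x):
        x = self.stem(x)
        p2 = self.stage2(self.down2(x))
        p3 = self.stage3(self.down3(p2))
        p4 = self.stage4(self.down4(p3))
        p5 = self.attn(self.sppf(self.stage5(self.down5(p4))))
        return {"P2": p2, "P3": p3, "P4": p4, "P5": p5}


# ---------------------------------------------------------------------------
# necks

class PAFPN(nn.Module):
    """Plain top-down + bottom-up aggregation neck over P3-P5."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        p = cfg.profile
        _, _, c3, c4, c5 = p.chans
        n = p.neck_depth
        lt4, lt3, lb4, lb5 = p.neck_lite
        self.up = nn.Upsample(2)
        self.td4 = CSPStage(c5 + c4, c4, n, shortcut=False, lite=lt4)
        self.td3 = CSPStage(c4 + c3, c3, n, shortcut=False, lite=lt3)
        self.down3 = nn.ConvBNAct(c3, c3, kernel=3, stride=2)
        self.bu4 = CSPStage(c3 + c4, c4, n, shortcut=False, lite=lb4)
        self.down4 = nn.ConvBNAct(c4, c4, kernel=3, stride=2)
        self.bu5 = CSPStage(c4 + c5, c5, n, shortcut=False, lite=lb5)

    def forward(self, feats):
        p3, p4, p5 = feats["P3"], feats["P4"], feats["P5"]
        t4 = self.td4(T.concat([self.up(p5), p4], axis=1))
        t3 = self.td3(T.concat([self.up(t4), p3], axis=1))
        b4 = self.bu4(T.concat([self.down3(t3), t4], axis=1))
        b5 = self.bu5(T.concat([self.down4(b4), p5], axis=1))
        return {"P3": t3, "P4": b4, "P5": b5}

    @property
    def out_channels(self):
        return {"P3": self.td3.cv2.conv.cout, "P4": self.bu4.cv2.conv.cout,
                "P5": self.bu5.cv2.conv.cout}


class FusionNode(nn.Module):
    """One IDFNet fusion node: sum the resampled inputs, pass through an
    AAFS gate, then a stride-1 3x3 convolution block."""

    def __init__(self, width: int, gate_groups: int):
        super().__init__()
        self.aafs = AAFS(AAFSConfig(width, gate_groups=gate_groups))
        self.conv = nn.ConvBNAct(width, width, kernel=3)

    def forward(self, inputs: list):
        s = inputs[0]
        for t in inputs[1:]:
            s = T.add(s, t)
        return self.conv(self.aafs(s))


class IDFLayer(nn.Module):
    """One repeat of the bidirectional weighted fusion over P3-P5.

    Top-down pass (P4, P3) then bottom-up pass (P4, P5); every node also
    receives the backbone feature of its level (the extra backbone-to-
    neck skip edges), and bottom-up nodes keep the layer-input skip.
    Levels may have different widths; 1x1 lateral convolutions map
    channels along the upsampling path and the stride-2 3x3 convolutions
    map them along the downsampling path."""

    def __init__(self, widths: tuple[int, int, int], gate_groups):
        super().__init__()
        w3, w4, w5 = widths
        g3, g4, g5 = [min(g, w) if g else w
                      for g, w in zip((gate_groups,) * 3, widths)]
        self.up = nn.Upsample(2)
        self.lat54 = nn.ConvBNAct(w5, w4, kernel=1)
        self.node_td4 = FusionNode(w4, g4)
        self.lat43 = nn.ConvBNAct(w4, w3, kernel=1)
        self.node_td3 = FusionNode(w3, g3)
        self.down3 = nn.ConvBNAct(w3, w4, kernel=3, stride=2)
        self.node_bu4 = FusionNode(w4, g4)
        self.down4 = nn.ConvBNAct(w4, w5, kernel=3, stride=2)
        self.node_bu5 = FusionNode(w5, g5)

    def forward(self, ins: dict, bb: dict) -> dict:
        td4 = self.node_td4([ins["P4"], self.up(self.lat54(ins["P5"])),
                             bb["P4"]])
        td3 = self.node_td3([ins["P3"], self.up(self.lat43(td4)), bb["P3"]])
        bu4 = self.node_bu4([ins["P4"], td4, self.down3(td3), bb["P4"]])
        bu5 = self.node_bu5([ins["P5"], self.down4(bu4), bb["P5"]])
        return {"P3": td3, "P4": bu4, "P5": bu5}


class IDFNet(nn.Module):
    """Repeated AAFS-gated bidirectional fusion with backbone skip edges."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        p = cfg.profile
        _, _, c3, c4, c5 = p.chans
        w = p.idf_width
        widths = (w, w, w) if isinstance(w, int) else tuple(w)
        self.align = nn.ModuleList([
            nn.ConvBNAct(c, wi, kernel=1)
            for c, wi in zip((c3, c4, c5), widths)])
        self.layers = nn.ModuleList([
            IDFLayer(widths, p.idf_gate_groups)
            for _ in range(cfg.neck_repeats)])
        self.widths = widths

    def forward(self, feats):
        bb = {lvl: conv(feats[lvl])
              for conv, lvl in zip(self.align, ("P3", "P4", "P5"))}
        x = dict(bb)
        for layer in self.layers:
            x = layer(x, bb)
        return x

    @property
    def out_channels(self):
        return {"P3": self.widths[0], "P4": self.widths[1],
                "P5": self.widths[2]}


class MFRoute(nn.Module):
    """Stride-4 small-target route: the neck's P5-path output is 2x
    upsampled three times (each step followed by a 3x3 convolution
    block), concatenated with backbone P2, and merged to the map feeding
    the added stride-4 head."""

    def __init__(self, cfg: ModelConfig, neck_p5_channels: int):
        super().__init__()
        p = cfg.profile
        c2 = p.chans[1]
        w = p.mf_width
        self.up = nn.Upsample(2)
        self.conv1 = nn.ConvBNAct(neck_p5_channels, w, kernel=3)
        self.conv2 = nn.ConvBNAct(w, w, kernel=3)
        self.conv3 = nn.ConvBNAct(w, w, kernel=3)
        self.fuse = CSPStage(w + c2, w, 1, shortcut=False)
        self.width = w

    def forward(self, neck_p5, backbone_p2):
        x = self.conv1(self.up(neck_p5))
        x = self.conv2(self.up(x))
        x = self.conv3(self.up(x))
        if not T.is_probe(x):
            assert x.shape[2:] == backbone_p2.shape[2:], \
                f"MF route resolution {x.shape} vs P2 {backbone_p2.shape}"
        return self.fuse(T.concat([x, backbone_p2], axis=1))


# ---------------------------------------------------------------------------
# heads

class LevelHead(nn.Module):
    """Decoupled head for one pyramid level: a class branch and a binned
    box-regression branch (reg_max bins per side)."""

    def __init__(self, cin: int, num_classes: int, reg_width: int,
                 cls_width: int, reg_max: int, cls_separable: bool):
        super().__init__()
        self.reg = nn.Sequential(
            nn.ConvBNAct(cin, reg_width, kernel=3),
            nn.ConvBNAct(reg_width, reg_width, kernel=3),
            nn.Conv2d(reg_width, 4 * reg_max, kernel=1))
        if cls_separable:
            self.cls = nn.Sequential(
                nn.ConvBNAct(cin, cin, kernel=3, groups=cin),
                nn.ConvBNAct(cin, cls_width, kernel=1),
                nn.ConvBNAct(cls_width, cls_width, kernel=3,
                             groups=cls_width),
                nn.ConvBNAct(cls_width, cls_width, kernel=1),
                nn.Conv2d(cls_width, num_classes, kernel=1))
        else:
            self.cls = nn.Sequential(
                nn.ConvBNAct(cin, cls_width, kernel=3),
                nn.ConvBNAct(cls_width, cls_width, kernel=3),
                nn.Conv2d(cls_width, num_classes, kernel=1))
        # rare-foreground prior: start class probabilities near 1%
        self.cls[-1].bias.data[...] = -math.log((1 - 0.01) / 0.01)
        # small-box prior: bias the side-distance distributions toward the
        # low bins so initial boxes are compact (about 0.6 stride units),
        # which gives small targets usable IoU from the first epoch
        self.reg[-1].bias.data[...] = np.tile(
            -np.arange(reg_max, dtype=np.float32), 4)

    def forward(self, x):
        return self.cls(x), self.reg(x)


class DetectionHead(nn.Module):
    """Per-level heads, duplicated into a densely supervised one-to-many
    set and a one-to-one set for NMS-free inference."""

    def __init__(self, cfg: ModelConfig, in_channels: list[int]):
        super().__init__()
        p = cfg.profile
        nlev = len(in_channels)

        def per_level(w):
            if isinstance(w, int):
                return (w,) * nlev
            # tuples are listed for 4 levels (P2..P5); drop P2 when absent
            return tuple(w[-nlev:])

        rws = per_level(p.head_reg_width)
        cws = per_level(p.head_cls_width)

        def mk():
            return nn.ModuleList([
                LevelHead(c, cfg.num_classes, rw, cw, p.reg_max,
                          p.cls_separable)
                for c, rw, cw in zip(in_channels, rws, cws)])

        self.one2many = mk()
        self.one2one = mk()

    def forward(self, feats: list):
        return {
            "one2many": [h(f) for h, f in zip(self.one2many, feats)],
            "one2one": [h(f) for h, f in zip(self.one2one, feats)],
        }


# ---------------------------------------------------------------------------
# full model

class Detector(nn.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        self.backbone = Backbone(cfg)
        self.neck = IDFNet(cfg) if cfg.use_idfnet else PAFPN(cfg)
        neck_ch = self.neck.out_channels
        head_in = [neck_ch["P3"], neck_ch["P4"], neck_ch["P5"]]
        if cfg.use_mflayer:
            self.mf = MFRoute(cfg, neck_ch["P5"])
            head_in = [self.mf.width] + head_in
        else:
            self.mf = None
        self.head = DetectionHead(cfg, head_in)
        self.strides = list(cfg.head_strides)

    def forward(self, x):
        bb = self.backbone(x)
        neck = self.neck(bb)
        feats = [neck["P3"], neck["P4"], neck["P5"]]
        if self.mf is not None:
            feats = [self.mf(neck["P5"], bb["P2"])] + feats
        out = self.head(feats)
        out["strides"] = self.strides
        return out


def build_model(cfg: ModelConfig) -> Detector:
    return Detector(cfg)


# ---------------------------------------------------------------------------
# decoding

def decode_level(cls_logits, reg_logits, stride: int, input_size: int,
                 reg_max: int = 16):
    """Decode one level's raw maps to normalized (cx, cy, w, h) boxes and
    class probabilities.

    Regression bins are distances (in stride units) from the cell center
    to the four box sides; the expected value of the softmax distribution
    gives the distance.  Returns numpy arrays (N, cells, 4) and
    (N, cells, nc); boxes are clipped to the unit square.
    """
    cls = cls_logits.data if isinstance(cls_logits, T.Tensor) else cls_logits
    reg = reg_logits.data if isinstance(reg_logits, T.Tensor) else reg_logits
    n, nc, h, w = cls.shape
    prob = 1.0 / (1.0 + np.exp(-np.clip(
        cls.reshape(n, nc, h * w).transpose(0, 2, 1), -60, 60)))
    d = reg.reshape(n, 4, reg_max, h, w)
    d = d - d.max(axis=2, keepdims=True)
    e = np.exp(d)
    dist = (e / e.sum(axis=2, keepdims=True) *
            np.arange(reg_max, dtype=np.float32)[None, None, :, None, None]
            ).sum(axis=2)  # (n, 4, h, w) in stride units: l, t, r, b
    ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    cx = (xs[None] + 0.5 - dist[:, 0] + xs[None] + 0.5 + dist[:, 2]) / 2
    cy = (ys[None] + 0.5 - dist[:, 1] + ys[None] + 0.5 + dist[:, 3]) / 2
    bw = dist[:, 0] + dist[:, 2]
    bh = dist[:, 1] + dist[:, 3]
    boxes = np.stack([cx, cy, bw, bh], axis=-1) * stride / float(input_size)
    boxes = boxes.reshape(n, h * w, 4)
    # clip to unit square, preserving positive size
    x1 = np.clip(boxes[..., 0] - boxes[..., 2] / 2, 0.0, 1.0)
    y1 = np.clip(boxes[..., 1] - boxes[..., 3] / 2, 0.0, 1.0)
    x2 = np.clip(boxes[..., 0] + boxes[..., 2] / 2, 0.0, 1.0)
    y2 = np.clip(boxes[..., 1] + boxes[..., 3] / 2, 0.0, 1.0)
    boxes = np.stack([(x1 + x2) / 2, (y1 + y2) / 2,
                      np.maximum(x2 - x1, 1e-6),
                      np.maximum(y2 - y1, 1e-6)], axis=-1)
    return boxes.astype(np.float32), prob.astype(np.float32)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float = 0.5
        ) -> list[int]:
    """Greedy non-maximum suppression on (n, 4) cxcywh boxes; returns
    kept indices in descending score order."""
    from .metrics import iou_cxcywh
    order = np.argsort(-scores, kind="stable")
    keep: list[int] = []
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        rest = order[1:]
        ious = iou_cxcywh(boxes[rest], boxes[i][None])
        order = rest[ious < iou_thresh]
    return keep


def predict(model: Detector, images: np.ndarray, score_thresh: float = 0.25,
            topk: int = 300, branch: str = "one2one",
            use_nms: bool = False, nms_iou: float = 0.5):
    """Decode a head branch into per-image detections.

    Default is NMS-free: the one-to-one branch with top-k selection.
    ``branch="one2many", use_nms=True`` gives the conventional densely
    supervised path with greedy suppression.  Returns a list (per
    image) of dicts with keys class_id, score, box (normalized
    cx, cy, w, h)."""
    model.eval()
    out = model(T.Tensor(images))
    input_size = images.shape[-1]
    reg_max = model.cfg.profile.reg_max
    all_boxes, all_scores = [], []
    for (cls, reg), stride in zip(out[branch], out["strides"]):
        b, p = decode_level(cls, reg, stride, input_size, reg_max)
        all_boxes.append(b)
        all_scores.append(p)
    boxes = np.concatenate(all_boxes, axis=1)
    scores = np.concatenate(all_scores, axis=1)
    results = []
    for i in range(boxes.shape[0]):
        sc = scores[i]
        cls_id = sc.argmax(axis=1)
        conf = sc.max(axis=1)
        order = np.argsort(-conf, kind="stable")[:topk]
        order = order[conf[order] >= score_thresh]
        if use_nms and order.size:
            kept = []
            for c in np.unique(cls_id[order]):
                sel = order[cls_id[order] == c]
                kept.extend(sel[k] for k in nms(boxes[i, sel], conf[sel],
                                                nms_iou))
            order = np.array(sorted(kept, key=lambda j: -conf[j]), dtype=int)
        dets = [{"class_id": int(cls_id[j]), "score": float(conf[j]),
                 "box": tuple(float(v) for v in boxes[i, j])}
                for j in order]
        results.append(dets)
    return results
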