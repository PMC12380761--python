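"""Training loop and validation glue.

Optimization follows the single-stage detector convention: SGD with
momentum 0.937 and weight decay 5e-4, initial learning rate 0.01,
batch 16, 100 epochs at 640 px input.  Two schedules are available —
cosine annealing with warm restarts (default) and exponential decay
lr0 * alpha**epoch with alpha 0.95 — because both appear in the
training recipe this package reconstructs; the choice is a config
field.  Training never loads external pretrained weights.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .nn import tensor as T
from .augment import AugmentConfig, augment, oversampling_weights
from .data import Box
from .losses import AssignerConfig, LossWeights, detection_loss
from .metrics import EvalReport, evaluate
from .model import Detector, ModelConfig, predict


@dataclass
class TrainConfig:
    lr0: float = 0.01
    batch_size: int = 16
    momentum: float = 0.937
    weight_decay: float = 0.0005
    epochs: int = 100
    input_size: int = 640
    scheduler: str = "cosine"        # "cosine" | "exponential"
    alpha: float = 0.95              # exponential decay factor
    cosine_t0: int = 10
    cosine_t_mult: int = 2
    warmup_epochs: int = 0           # optional linear lr ramp from lr0/10
    seed: int = 0
    pretrained: bool = False
    augment: AugmentConfig | None = None
    loss_weights: LossWeights = field(default_factory=LossWeights)
    assigner: AssignerConfig = field(default_factory=AssignerConfig)
    eval_interval: int = 1           # epochs between validation passes
    oversample: bool = False

    def __post_init__(self):
        if self.pretrained:
            raise ValueError("pretrained weights are not supported: "
                             "training always starts from random init")
        if self.scheduler not in ("cosine", "exponential"):
            raise ValueError(f"unknown scheduler {self.scheduler!r}")

    def lr_at(self, epoch: int) -> float:
        if self.scheduler == "exponential":
            lr = nn.ExponentialDecay(self.lr0, self.alpha).lr(epoch)
        else:
            lr = nn.CosineWarmRestarts(self.lr0, self.cosine_t0,
                                       self.cosine_t_mult).lr(epoch)
        if epoch < self.warmup_epochs:
            ramp = (0.1 + 0.9 * (epoch + 1) / self.warmup_epochs)
            lr *= ramp
        return lr


class NonFiniteLoss(RuntimeError):
    pass


def _prepare_image(img: np.ndarray, size: int) -> np.ndarray:
    if img.shape[0] != size or img.shape[1] != size:
        img = np.asarray(Image.fromarray(img).resize((size, size),
                                                     Image.BILINEAR))
    return (img.astype(np.float32) / 255.0).transpose(2, 0, 1)


def _boxes_to_targets(boxes: list[Box]):
    return [(b.class_id, np.array([b.cx, b.cy, b.w, b.h], np.float32))
            for b in boxes]


def evaluate_model(model: Detector, val_data, num_classes: int,
                   input_size: int, score_thresh: float = 0.02,
                   class_names: list[str] | None = None,
                   branch: str = "one2many",
                   use_nms: bool = True) -> EvalReport:
    """Run inference over a split and score it.

    Defaults to the densely supervised branch with NMS (the more robust
    path for lightly trained models); NMS-free one-to-one inference is
    available via branch/use_nms."""
    dets, gts = [], []
    bs = 8
    for i in range(0, len(val_data), bs):
        chunk = val_data[i:i + bs]
        batch = np.stack([_prepare_image(img, input_size)
                          for img, _ in chunk])
        res = predict(model, batch, score_thresh=score_thresh,
                      branch=branch, use_nms=use_nms)
        dets.extend(res)
        gts.extend([_boxes_to_targets(b) for _, b in chunk])
    return evaluate(dets, gts, num_classes, class_names=class_names)


def recalibrate_bn(model: Detector, data, input_size: int,
                   batch_size: int = 16, max_batches: int = 16) -> None:
    """Re-estimate batch-norm running statistics under the current
    weights (precise-BN): replaces the lagging exponential averages
    accumulated during optimization with the plain average of batch
    statistics over up to `max_batches` training batches."""
    bns = [m for m in model.modules() if isinstance(m, nn.BatchNorm2d)]
    if not bns:
        return
    saved_flags = [p.requires_grad for p in model.parameters()]
    for p in model.parameters():
        p.requires_grad = False
    for bn in bns:
        bn.running_mean[...] = 0.0
        bn.running_var[...] = 0.0
    model.train()
    n = 0
    for start in range(0, min(len(data), batch_size * max_batches),
                       batch_size):
        chunk = data[start:start + batch_size]
        n += 1
        for bn in bns:
            bn.momentum = 1.0 / n      # cumulative moving average
        batch = np.stack([_prepare_image(img, input_size)
                          for img, _ in chunk])
        model(T.Tensor(batch))
    for bn in bns:
        bn.momentum = 0.03
    for p, f in zip(model.parameters(), saved_flags):
        p.requires_grad = f


def train(model: Detector, train_data, cfg: TrainConfig,
          val_data=None, out_dir: str | Path | None = None,
          verbose: bool = False) -> list[dict]:
    """Train `model` on in-memory (image, boxes) pairs.

    Returns the per-epoch metric log (loss components, lr, validation
    mAP when computed).  With a fixed seed and single-threaded numpy the
    run is bit-reproducible.  A non-finite loss aborts with the first
    offending component named.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = nn.SGD(model.parameters(), lr=cfg.lr0, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    nc = model.cfg.num_classes
    reg_max = model.cfg.profile.reg_max
    log: list[dict] = []
    best_map = -1.0

    weights = None
    if cfg.oversample:
        counts: dict[int, int] = {}
        for _, boxes in train_data:
            for b in boxes:
                counts[b.class_id] = counts.get(b.class_id, 0) + 1
        w = oversampling_weights(counts)
        weights = np.array([
            max((w.get(b.class_id, 1.0) for b in boxes), default=1.0)
            for _, boxes in train_data])
        weights = weights / weights.sum()

    for epoch in range(cfg.epochs):
        lr = cfg.lr_at(epoch)
        opt.lr = lr
        model.train()
        if weights is not None:
            order = rng.choice(len(train_data), size=len(train_data),
                               replace=True, p=weights)
        else:
            order = rng.permutation(len(train_data))
        sums: dict[str, float] = {}
        nb = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            imgs, tgts = [], []
            for j in idx:
                img, boxes = train_data[j]
                if cfg.augment is not None:
                    img, boxes = augment(img, boxes, cfg.augment,
                                         seed=int(rng.integers(2 ** 31)))
                imgs.append(_prepare_image(img, cfg.input_size))
                tgts.append(_boxes_to_targets(boxes))
            batch = np.stack(imgs)
            model.zero_grad()
            loss, comps = detection_loss(
                model(T.Tensor(batch)), tgts, cfg.input_size,
                reg_max=reg_max, weights=cfg.loss_weights,
                assigner=cfg.assigner)
            if not np.isfinite(loss.data):
                bad = [k for k, v in comps.items()
                       if isinstance(v, float) and not np.isfinite(v)]
                raise NonFiniteLoss(
                    f"non-finite loss at epoch {epoch}: first bad "
                    f"component(s) {bad or ['total']}")
            loss.backward()
            opt.step()
            nb += 1
            for k, v in comps.items():
                if isinstance(v, float):
                    sums[k] = sums.get(k, 0.0) + v
        entry = {"epoch": epoch, "lr": lr,
                 **{k: v / nb for k, v in sums.items()}}
        if val_data is not None and (epoch + 1) % cfg.eval_interval == 0:
            recalibrate_bn(model, train_data, cfg.input_size,
                           cfg.batch_size)
            report = evaluate_model(model, val_data, nc, cfg.input_size)
            entry["map50"] = report.map50
            entry["map5095"] = report.map5095
            if out is not None and report.map50 > best_map:
                best_map = report.map50
                save_checkpoint(out / "best.npz", model)
        log.append(entry)
        if verbose:
            print(json.dumps({k: round(v, 4) if isinstance(v, float) else v
                              for k, v in entry.items()}))
        if out is not None:
            with (out / "log.jsonl").open("a") as fh:
                fh.write(json.dumps(entry) + "\n")
    recalibrate_bn(model, train_data, cfg.input_size, cfg.batch_size)
    if out is not None:
        save_checkpoint(out / "last.npz", model)
    return log


def save_checkpoint(path: str | Path, model: Detector) -> None:
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path: str | Path) -> Detector:
    from .model import build_model
    data = np.load(path)
    cfg_dict = json.loads(bytes(data["__config__"]).decode())
    prof = cfg_dict.pop("profile", None)
    cfg = ModelConfig(**{k: v for k, v in cfg_dict.items()
                         if k != "profile"})
    if prof is not None:
        from .topology import WidthProfile
        prof = {k: tuple(v) if isinstance(v, list) else v
                for k, v in prof.items()}
        cfg.profile = WidthProfile(**prof)
    model = build_model(cfg)
    model.load_state_dict({k: data[k] for k in data.files
                           if k != "__config__"})
    return model
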