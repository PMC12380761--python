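"""Training-time augmentation with box-consistent geometry.

Geometric transforms (flips, small rotations, mosaic) remap boxes;
photometric jitter (brightness/contrast/saturation) leaves them alone;
mixup blends two images and unions their labels.  Degenerate boxes
produced by clipping are dropped and counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .data import Box


@dataclass
class AugmentConfig:
    rotation_limit: float = 15.0      # degrees, +/-
    hflip: bool = True
    vflip: bool = True
    brightness: float = 0.25          # +/- fraction
    contrast: float = 0.20
    saturation: float = 0.15
    mosaic: bool = False
    mixup: bool = False
    mixup_beta: float = 8.0           # lambda ~ Beta(b, b)
    min_box_area: float = 4e-5        # normalized area below which boxes drop
    oversample_minority: bool = False

    def __post_init__(self):
        if not (0 <= self.rotation_limit <= 15.0):
            raise ValueError("rotation limit must be within +/-15 degrees")
        if self.brightness > 0.25 or self.contrast > 0.20 or self.saturation > 0.15:
            raise ValueError("photometric jitter exceeds configured bounds")


#: number of boxes dropped because clipping degenerated them (diagnostic)
DROPPED_BOXES = {"count": 0}


def hflip(image: np.ndarray, boxes: list[Box]) -> tuple[np.ndarray, list[Box]]:
    return image[:, ::-1].copy(), [
        Box(b.class_id, 1.0 - b.cx, b.cy, b.w, b.h) for b in boxes]


def vflip(image: np.ndarray, boxes: list[Box]) -> tuple[np.ndarray, list[Box]]:
    return image[::-1].copy(), [
        Box(b.class_id, b.cx, 1.0 - b.cy, b.w, b.h) for b in boxes]


def rotate(image: np.ndarray, boxes: list[Box], angle: float,
           min_area: float = 4e-5) -> tuple[np.ndarray, list[Box]]:
    """Rotate about the image center; boxes recomputed from transformed
    corners and clipped to the unit square."""
    out = ndimage.rotate(image, angle, reshape=False, order=1,
                         mode="constant", cval=0)
    th = math.radians(angle)
    cos, sin = math.cos(th), math.sin(th)
    new_boxes = []
    for b in boxes:
        xs = np.array([b.cx - b.w / 2, b.cx + b.w / 2] * 2) - 0.5
        ys = np.array([b.cy - b.h / 2] * 2 + [b.cy + b.h / 2] * 2) - 0.5
        # image rotation by +angle moves content by -angle in coords
        rx = xs * cos + ys * sin + 0.5
        ry = -xs * sin + ys * cos + 0.5
        x1, x2 = np.clip(rx.min(), 0, 1), np.clip(rx.max(), 0, 1)
        y1, y2 = np.clip(ry.min(), 0, 1), np.clip(ry.max(), 0, 1)
        w, h = x2 - x1, y2 - y1
        if w * h < min_area:
            DROPPED_BOXES["count"] += 1
            continue
        new_boxes.append(Box(b.class_id, (x1 + x2) / 2, (y1 + y2) / 2, w, h))
    return out, new_boxes


def photometric(image: np.ndarray, rng: np.random.Generator,
                cfg: AugmentConfig) -> np.ndarray:
    """Brightness/contrast/saturation jitter within configured bounds."""
    img = image.astype(np.float32)
    img = img * (1.0 + rng.uniform(-cfg.brightness, cfg.brightness))
    mean = img.mean()
    img = (img - mean) * (1.0 + rng.uniform(-cfg.contrast, cfg.contrast)) + mean
    gray = img.mean(axis=2, keepdims=True)
    img = gray + (img - gray) * (1.0 + rng.uniform(-cfg.saturation,
                                                   cfg.saturation))
    return np.clip(img, 0, 255).astype(np.uint8)


def mixup(image_a: np.ndarray, boxes_a: list[Box],
          image_b: np.ndarray, boxes_b: list[Box],
          lam: float) -> tuple[np.ndarray, list[Box]]:
    """Convex blend lam*A + (1-lam)*B; labels are united."""
    img = (lam * image_a.astype(np.float32)
           + (1.0 - lam) * image_b.astype(np.float32))
    return np.clip(img, 0, 255).astype(np.uint8), list(boxes_a) + list(boxes_b)


def mosaic(items: list[tuple[np.ndarray, list[Box]]],
           rng: np.random.Generator,
           min_area: float = 4e-5) -> tuple[np.ndarray, list[Box]]:
    """Compose 4 images into a 2x2 canvas (each tile keeps its source
    resolution, canvas is 2x the tile side) and remap all boxes."""
    assert len(items) == 4
    s = items[0][0].shape[0]
    canvas = np.zeros((2 * s, 2 * s, 3), dtype=np.uint8)
    boxes: list[Box] = []
    for k, (img, bxs) in enumerate(items):
        oy, ox = (k // 2) * s, (k % 2) * s
        canvas[oy:oy + s, ox:ox + s] = img
        for b in bxs:
            w, h = b.w / 2, b.h / 2
            if w * h < min_area:
                DROPPED_BOXES["count"] += 1
                continue
            boxes.append(Box(b.class_id, (b.cx * s + ox) / (2 * s),
                             (b.cy * s + oy) / (2 * s), w, h))
    return canvas, boxes


def augment(image: np.ndarray, boxes: list[Box], cfg: AugmentConfig,
            seed: int) -> tuple[np.ndarray, list[Box]]:
    """Apply the configured pipeline with an explicit RNG seed."""
    rng = np.random.default_rng(seed)
    if cfg.hflip and rng.random() < 0.5:
        image, boxes = hflip(image, boxes)
    if cfg.vflip and rng.random() < 0.5:
        image, boxes = vflip(image, boxes)
    if cfg.rotation_limit > 0:
        angle = float(rng.uniform(-cfg.rotation_limit, cfg.rotation_limit))
        image, boxes = rotate(image, boxes, angle, cfg.min_box_area)
    image = photometric(image, rng, cfg)
    return image, boxes


def oversampling_weights(class_counts: dict[int, int]) -> dict[int, float]:
    """Sampling-with-replacement weights proportional to inverse class
    frequency; uniform for a balanced set."""
    total = sum(class_counts.values())
    k = len(class_counts)
    return {c: total / (k * n) if n else 0.0 for c, n in class_counts.items()}
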