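"""Synthetic greenhouse scene generator.

No public vegetable-disease detection corpus matches the structure this
package targets (15 classes = 3 crops x 5 conditions including healthy,
7:2:1 splits, a heavy tail of sub-20-pixel lesions, leaf occlusion,
uneven greenhouse illumination, sensor noise), so the generator emulates
that *structure* — not the appearance of any real dataset.  Scenes are
procedurally drawn: elliptical leaves over a soil background, small
elliptical lesions constrained to lie on their parent leaf, a smooth
multiplicative illumination field with specular highlight spots, then
Gaussian and salt-and-pepper noise.

Ground-truth convention: each lesion yields one box of its disease
class; each lesion-free leaf yields one box of its crop's healthy class.
Everything is a deterministic function of the scene seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from .data import Box, DatasetDescriptor, save_image, write_yolo_labels

CROPS = ("tomato", "cucumber", "pepper")
CONDITIONS = ("health", "gray_mold", "leaf_spot", "black_spot", "blight")

#: 15 default classes: crop-major order, condition 0 is healthy.
CLASS_NAMES = [f"{code}{i + 1}_{crop}_{cond}"
               for code, crop in zip("ABC", CROPS)
               for i, cond in enumerate(CONDITIONS)]

_CROP_GREENS = {  # base leaf RGB per crop
    0: (58, 122, 48),
    1: (44, 138, 62),
    2: (70, 132, 40),
}
_LESION_COLORS = {  # per condition (1..4)
    1: (128, 118, 104),   # gray mold
    2: (142, 126, 60),    # leaf spot (yellowish)
    3: (52, 40, 30),      # black spot
    4: (110, 66, 42),     # blight (brown)
}


class SceneError(ValueError):
    pass


@dataclass
class Leaf:
    center: tuple[float, float]     # pixels (x, y)
    axes: tuple[float, float]       # semi-axes (a, b) pixels
    angle: float                    # degrees
    color: tuple[int, int, int]


@dataclass
class Lesion:
    leaf_index: int
    class_id: int
    center: tuple[float, float]     # pixels (x, y)
    radius: float                   # pixels
    aspect: float = 1.0             # minor/major axis ratio
    angle: float = 0.0


@dataclass
class IlluminationSpec:
    direction: float = 0.0          # degrees, gradient direction
    strength: float = 0.0           # 0 = identity
    spots: list[tuple[float, float, float, float]] = field(default_factory=list)
    # each spot: (x, y, sigma_px, gain)


@dataclass
class NoiseSpec:
    gaussian_sigma: float = 0.0     # fraction of dynamic range, [0.1, 0.3] when on
    salt_pepper: float = 0.0        # corrupted-pixel fraction


@dataclass
class SceneSpec:
    image_size: int
    crop: int
    leaves: list[Leaf]
    lesions: list[Lesion]
    illumination: IlluminationSpec
    noise: NoiseSpec
    seed: int

    def validate(self) -> None:
        for les in self.lesions:
            if not 0 <= les.leaf_index < len(self.leaves):
                raise SceneError(f"lesion parent {les.leaf_index} out of range")
            leaf = self.leaves[les.leaf_index]
            if _ellipse_value(les.center, leaf) > 0.85:
                raise SceneError(
                    f"lesion at {les.center} lies outside its parent leaf")


def _ellipse_value(point, leaf: Leaf) -> float:
    """Normalized ellipse coordinate of a point (<=1 means inside)."""
    th = math.radians(leaf.angle)
    dx, dy = point[0] - leaf.center[0], point[1] - leaf.center[1]
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    return math.sqrt((u / leaf.axes[0]) ** 2 + (v / leaf.axes[1]) ** 2)


def _ellipse_mask(size: int, center, axes, angle: float) -> np.ndarray:
    ys, xs = np.mgrid[0:size, 0:size]
    th = math.radians(angle)
    dx, dy = xs - center[0], ys - center[1]
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _leaf_bbox(leaf: Leaf, size: int) -> tuple[float, float, float, float]:
    """Axis-aligned bbox (normalized cxcywh) of a rotated ellipse, clipped."""
    th = math.radians(leaf.angle)
    hx = math.sqrt((leaf.axes[0] * math.cos(th)) ** 2 +
                   (leaf.axes[1] * math.sin(th)) ** 2)
    hy = math.sqrt((leaf.axes[0] * math.sin(th)) ** 2 +
                   (leaf.axes[1] * math.cos(th)) ** 2)
    return _clip_box(leaf.center[0], leaf.center[1], 2 * hx, 2 * hy, size)


def _clip_box(cx, cy, w, h, size) -> tuple[float, float, float, float]:
    x1 = max(0.0, cx - w / 2)
    y1 = max(0.0, cy - h / 2)
    x2 = min(float(size), cx + w / 2)
    y2 = min(float(size), cy + h / 2)
    return ((x1 + x2) / 2 / size, (y1 + y2) / 2 / size,
            max(x2 - x1, 1.0) / size, max(y2 - y1, 1.0) / size)


# ---------------------------------------------------------------------------
# rendering

def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, list[Box]]:
    """Render the scene; returns (uint8 RGB image, ground-truth boxes).

    Deterministic: the same spec produces byte-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    # soil-like background with a gentle vertical tone sweep and texture
    base = np.array([92, 76, 58], dtype=np.float32)
    img = np.empty((s, s, 3), dtype=np.float32)
    img[:] = base
    img += (np.linspace(-12, 12, s)[:, None, None]
            * np.array([1.0, 0.8, 0.6])[None, None, :])
    img += rng.normal(0, 6, size=(s, s, 1)).astype(np.float32)

    lesions_by_leaf: dict[int, list[Lesion]] = {}
    for les in spec.lesions:
        lesions_by_leaf.setdefault(les.leaf_index, []).append(les)

    visible = []  # per-leaf mask after occlusion by later leaves
    for li, leaf in enumerate(spec.leaves):
        mask = _ellipse_mask(s, leaf.center, leaf.axes, leaf.angle)
        visible.append(mask)
        color = np.array(leaf.color, dtype=np.float32)
        # radial shading toward the rim + vein-ish texture
        ys, xs = np.mgrid[0:s, 0:s]
        r = np.hypot(xs - leaf.center[0], ys - leaf.center[1])
        shade = 1.0 - 0.25 * np.clip(r / (max(leaf.axes) + 1e-6), 0, 1)
        tex = rng.normal(0, 4, size=(s, s)).astype(np.float32)
        for c in range(3):
            img[:, :, c][mask] = color[c] * shade[mask] + tex[mask]
        for les in lesions_by_leaf.get(li, []):
            lmask = _ellipse_mask(s, les.center,
                                  (les.radius, les.radius * les.aspect),
                                  les.angle)
            lcol = np.array(_LESION_COLORS[les.class_id % 5], dtype=np.float32)
            ring = _ellipse_mask(s, les.center,
                                 (les.radius * 1.3, les.radius * les.aspect * 1.3),
                                 les.angle) & ~lmask
            for c in range(3):
                img[:, :, c][lmask] = lcol[c] + rng.normal(0, 5)
                img[:, :, c][ring] = 0.5 * img[:, :, c][ring] + 0.5 * (lcol[c] + 25)

    img = np.clip(img, 0, 255)
    img = apply_illumination(img, spec.illumination)
    img = add_gaussian_noise(img, spec.noise.gaussian_sigma,
                             int(rng.integers(2 ** 31)))
    img = add_salt_pepper(img, spec.noise.salt_pepper,
                          int(rng.integers(2 ** 31)))

    boxes: list[Box] = []
    healthy_class = spec.crop * 5
    for li, leaf in enumerate(spec.leaves):
        if li not in lesions_by_leaf:
            boxes.append(Box(healthy_class, *_leaf_bbox(leaf, s)))
    for les in spec.lesions:
        boxes.append(Box(les.class_id,
                         *_clip_box(les.center[0], les.center[1],
                                    2 * les.radius, 2 * les.radius, s)))
    return img.astype(np.uint8), boxes


def apply_illumination(image: np.ndarray, spec: IlluminationSpec) -> np.ndarray:
    """Multiply by a planar gradient field plus Gaussian highlight spots.

    strength 0 with no spots is the identity; output clipped to [0, 255].
    """
    if spec.strength == 0 and not spec.spots:
        return image
    img = image.astype(np.float32)
    h, w = img.shape[:2]
    field_ = np.ones((h, w), dtype=np.float32)
    if spec.strength > 0:
        th = math.radians(spec.direction)
        ys, xs = np.mgrid[0:h, 0:w]
        proj = (xs * math.cos(th) + ys * math.sin(th))
        proj = (proj - proj.min()) / max(np.ptp(proj), 1e-9) - 0.5
        field_ += spec.strength * proj
    for (sx, sy, sig, gain) in spec.spots:
        ys, xs = np.mgrid[0:h, 0:w]
        field_ += gain * np.exp(-((xs - sx) ** 2 + (ys - sy) ** 2)
                                / (2 * sig ** 2)).astype(np.float32)
    return np.clip(img * field_[:, :, None], 0, 255).astype(image.dtype)


def add_gaussian_noise(image: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Zero-mean Gaussian noise, std = sigma x 255, clipped; sigma 0 = identity."""
    if sigma <= 0:
        return image
    rng = np.random.default_rng(seed)
    noisy = image.astype(np.float32) + rng.normal(0, sigma * 255.0,
                                                  size=image.shape)
    return np.clip(noisy, 0, 255).astype(image.dtype)


def add_salt_pepper(image: np.ndarray, density: float, seed: int) -> np.ndarray:
    """Set ~density of pixels to 0 or 255 (equal probability); 0 = identity."""
    if density <= 0:
        return image
    if not 0 <= density <= 1:
        raise ValueError(f"density must be in [0,1], got {density}")
    rng = np.random.default_rng(seed)
    h, w = image.shape[:2]
    u = rng.random((h, w))
    out = image.copy()
    out[u < density / 2] = 0
    out[(u >= density / 2) & (u < density)] = 255
    return out


# ---------------------------------------------------------------------------
# scene sampling

@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic corpus.

    Lesion radii are log-uniform; `small_fraction` of lesions are drawn
    below 10 px radius so sub-20-px targets dominate, matching the
    micro-lesion emphasis of greenhouse imagery.  Gaussian noise sigma
    is drawn per image from `sigma_range` (fraction of dynamic range).
    """

    image_size: int = 640
    min_leaves: int = 1
    max_leaves: int = 3
    min_lesions: int = 1
    max_lesions: int = 4
    lesion_radius_range: tuple[float, float] = (3.0, 24.0)
    small_fraction: float = 0.6     # fraction of lesions with radius < 10 px
    small_radius_max: float = 10.0
    occlusion_prob: float = 0.5     # chance extra leaves overlap the primary
    illum_strength_range: tuple[float, float] = (0.0, 0.35)
    highlight_prob: float = 0.5
    sigma_range: tuple[float, float] = (0.1, 0.3)
    salt_pepper: float = 0.01


def sample_scene(class_id: int, seed: int,
                 cfg: GeneratorConfig | None = None) -> SceneSpec:
    """Draw a random SceneSpec whose primary annotation class is `class_id`."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    s = cfg.image_size
    crop = class_id // 5
    condition = class_id % 5
    n_leaves = int(rng.integers(cfg.min_leaves, cfg.max_leaves + 1))
    leaves = []
    cx0, cy0 = rng.uniform(0.35 * s, 0.65 * s, size=2)
    for i in range(n_leaves):
        if i == 0:
            cx, cy = cx0, cy0
        elif rng.random() < cfg.occlusion_prob:
            cx = cx0 + rng.uniform(-0.25 * s, 0.25 * s)
            cy = cy0 + rng.uniform(-0.25 * s, 0.25 * s)
        else:
            cx, cy = rng.uniform(0.2 * s, 0.8 * s, size=2)
        a = rng.uniform(0.14 * s, 0.30 * s)
        b = a * rng.uniform(0.55, 0.85)
        jitter = rng.integers(-18, 18, size=3)
        color = tuple(int(np.clip(c + j, 20, 200))
                      for c, j in zip(_CROP_GREENS[crop], jitter))
        leaves.append(Leaf((float(cx), float(cy)), (float(a), float(b)),
                           float(rng.uniform(0, 180)), color))

    lesions: list[Lesion] = []
    if condition != 0:
        n_les = int(rng.integers(cfg.min_lesions, cfg.max_lesions + 1))
        leaf = leaves[0]
        rmin, rmax = cfg.lesion_radius_range
        for _ in range(n_les):
            if rng.random() < cfg.small_fraction:
                lo, hi = rmin, min(cfg.small_radius_max, rmax)
            else:
                lo, hi = min(cfg.small_radius_max, rmax), rmax
            radius = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            # rejection-sample a point well inside the parent ellipse
            for _ in range(100):
                t = rng.uniform(0, 2 * math.pi)
                rr = math.sqrt(rng.uniform(0, 1)) * 0.7
                th = math.radians(leaf.angle)
                u = rr * leaf.axes[0] * math.cos(t)
                v = rr * leaf.axes[1] * math.sin(t)
                px = leaf.center[0] + u * math.cos(th) - v * math.sin(th)
                py = leaf.center[1] + u * math.sin(th) + v * math.cos(th)
                if 0 < px < s and 0 < py < s:
                    break
            lesions.append(Lesion(0, class_id, (float(px), float(py)), radius,
                                  aspect=float(rng.uniform(0.6, 1.0)),
                                  angle=float(rng.uniform(0, 180))))

    spots = []
    if rng.random() < cfg.highlight_prob:
        for _ in range(int(rng.integers(1, 3))):
            spots.append((float(rng.uniform(0, s)), float(rng.uniform(0, s)),
                          float(rng.uniform(0.08 * s, 0.2 * s)),
                          float(rng.uniform(0.15, 0.45))))
    illum = IlluminationSpec(direction=float(rng.uniform(0, 360)),
                             strength=float(rng.uniform(*cfg.illum_strength_range)),
                             spots=spots)
    noise = NoiseSpec(gaussian_sigma=float(rng.uniform(*cfg.sigma_range)),
                      salt_pepper=cfg.salt_pepper)
    return SceneSpec(s, crop, leaves, lesions, illum, noise,
                     seed=int(rng.integers(2 ** 31)))


# ---------------------------------------------------------------------------
# dataset on disk

def apportion(n: int, ratio: tuple[int, ...]) -> list[int]:
    """Largest-remainder apportionment of n items by an integer ratio."""
    total = sum(ratio)
    raw = [n * r / total for r in ratio]
    floors = [int(math.floor(x)) for x in raw]
    rem = n - sum(floors)
    order = sorted(range(len(ratio)), key=lambda i: raw[i] - floors[i],
                   reverse=True)
    for i in order[:rem]:
        floors[i] += 1
    return floors


def generate_dataset(n_images: int, out_dir: str | Path,
                     class_ids: list[int] | None = None,
                     ratio: tuple[int, int, int] = (7, 2, 1),
                     seed: int = 0,
                     cfg: GeneratorConfig | None = None,
                     names: list[str] | None = None) -> DatasetDescriptor:
    """Write a balanced annotated dataset split train/val/test by `ratio`.

    Images are cycled through the class list so per-class counts within
    every split differ by at most one.  Deterministic in `seed`: the
    same call produces byte-identical images and label files.
    """
    cfg = cfg or GeneratorConfig()
    out = Path(out_dir)
    class_ids = class_ids if class_ids is not None else list(range(15))
    names = names if names is not None else list(CLASS_NAMES)
    if any(r <= 0 for r in ratio):
        raise ValueError(f"ratio components must be positive: {ratio}")
    split_names = ("train", "val", "test")
    sizes = apportion(n_images, ratio)
    rng = np.random.default_rng(seed)
    desc = DatasetDescriptor(
        root=out,
        splits={sp: f"images/{sp}" for sp in split_names},
        names=names)
    counter = 0
    for sp, size in zip(split_names, sizes):
        img_dir = out / "images" / sp
        lab_dir = out / "labels" / sp
        img_dir.mkdir(parents=True, exist_ok=True)
        lab_dir.mkdir(parents=True, exist_ok=True)
        for i in range(size):
            cid = class_ids[i % len(class_ids)]
            spec = sample_scene(cid, seed=int(rng.integers(2 ** 31)), cfg=cfg)
            image, boxes = generate_scene(spec)
            stem = f"{sp}_{counter:06d}_c{cid:02d}"
            save_image(img_dir / f"{stem}.png", image)
            write_yolo_labels(lab_dir / f"{stem}.txt", boxes)
            counter += 1
    desc.to_yaml(out / "dataset.yaml")
    return desc
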