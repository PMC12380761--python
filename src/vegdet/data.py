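"""Dataset description and YOLO-format label IO.

Label dialect: one ``.txt`` per image with the same stem, one line per
box, ``class_id cx cy w h`` — normalized floats in [0, 1], center-based,
space-separated.  An empty (or absent) label file means a background
image.  The dataset YAML names the split directories, the class count
``nc`` and the ordered class-name list.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image


@dataclass
class Box:
    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.cx, self.cy, self.w, self.h)


class LabelFormatError(ValueError):
    pass


def read_yolo_labels(path: str | os.PathLike, nc: int | None = None) -> list[Box]:
    """Parse a YOLO label file; validates class range and coordinates."""
    path = Path(path)
    boxes: list[Box] = []
    if not path.exists():
        raise FileNotFoundError(path)
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise LabelFormatError(
                f"{path}:{ln}: expected 5 fields 'class cx cy w h', "
                f"got {len(parts)}")
        try:
            cid = int(parts[0])
            vals = [float(v) for v in parts[1:]]
        except ValueError as e:
            raise LabelFormatError(f"{path}:{ln}: {e}") from None
        if cid < 0 or (nc is not None and cid >= nc):
            raise LabelFormatError(
                f"{path}:{ln}: class id {cid} outside [0, {nc})")
        if any(v < 0.0 or v > 1.0 for v in vals):
            raise LabelFormatError(
                f"{path}:{ln}: coordinate outside [0, 1]: {vals}")
        boxes.append(Box(cid, *vals))
    return boxes


def write_yolo_labels(path: str | os.PathLike, boxes: list[Box]) -> None:
    lines = [f"{b.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}"
             for b in boxes]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


@dataclass
class DatasetDescriptor:
    root: Path
    splits: dict[str, str]          # split name -> image dir (relative to root)
    names: list[str]
    nc: int = 0

    def __post_init__(self):
        self.root = Path(self.root)
        if self.nc == 0:
            self.nc = len(self.names)
        if self.nc != len(self.names):
            raise ValueError(
                f"nc={self.nc} does not match {len(self.names)} class names")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "DatasetDescriptor":
        path = Path(path)
        d = yaml.safe_load(path.read_text())
        splits = {k: d[k] for k in ("train", "val", "test") if k in d}
        return cls(root=path.parent if "path" not in d else Path(d["path"]),
                   splits=splits, names=list(d["names"]), nc=int(d["nc"]))

    def to_yaml(self, path: str | os.PathLike) -> None:
        d = {"path": str(self.root), "nc": self.nc, "names": list(self.names)}
        d.update(self.splits)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def image_dir(self, split: str) -> Path:
        return self.root / self.splits[split]

    def label_dir(self, split: str) -> Path:
        return Path(str(self.image_dir(split)).replace("images", "labels"))

    def items(self, split: str) -> list[tuple[Path, Path]]:
        """(image path, label path) pairs, sorted by stem."""
        img_dir = self.image_dir(split)
        lab_dir = self.label_dir(split)
        pairs = []
        for p in sorted(img_dir.glob("*")):
            if p.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            pairs.append((p, lab_dir / f"{p.stem}.txt"))
        return pairs


def load_image(path: str | os.PathLike) -> np.ndarray:
    """uint8 RGB (H, W, 3)."""
    return np.asarray(Image.open(path).convert("RGB"))


def save_image(path: str | os.PathLike, image: np.ndarray) -> None:
    Image.fromarray(image.astype(np.uint8)).save(path)


def load_split(desc: DatasetDescriptor, split: str
               ) -> list[tuple[np.ndarray, list[Box]]]:
    """Materialize one split in memory (images are small in this package)."""
    out = []
    for img_path, lab_path in desc.items(split):
        boxes = read_yolo_labels(lab_path, nc=desc.nc) if lab_path.exists() else []
        out.append((load_image(img_path), boxes))
    return out
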