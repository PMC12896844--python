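"""Dataset I/O: images, Labelme polygon annotations, masks, manifests, splits.

Masks are stored as single-channel indexed PNGs (0 = background, 1 = torso,
2 = head, 3 = leg).  Polygon annotations follow the Labelme JSON layout
(``shapes[].label``, ``shapes[].points``) and are rasterized with a
pixel-center-in-polygon convention: the pixel at (row, col) belongs to a
polygon iff the point (col + 0.5, row + 0.5) lies strictly inside it.
Polygons are painted in file order, so later shapes overwrite earlier ones.

The train/val/test split operates on carcass identifiers, never on images,
so every image of one animal lands in exactly one subset (subject-independent
split).  For ratios (8, 1, 1) and n carcasses the rule is: floor(n/10) to
val, floor(n/10) to test, remainder to train.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from shapely.geometry import Polygon
from shapely import contains_xy

PART_CLASSES = {"background": 0, "torso": 1, "head": 2, "leg": 3}
CLASS_NAMES = {v: k for k, v in PART_CLASSES.items()}

# distinct palette colors per label index (indexed-PNG palette)
_DEFAULT_PALETTE = {0: (0, 0, 0), 1: (220, 60, 60), 2: (60, 180, 60), 3: (60, 90, 220)}


@dataclass
class LabelMask:
    """A per-pixel label image plus the label -> part-name mapping."""

    labels: np.ndarray
    class_map: dict[int, str] = field(default_factory=lambda: dict(CLASS_NAMES))

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        present = set(np.unique(self.labels).tolist())
        unknown = present - set(self.class_map)
        if unknown:
            raise ValueError(
                f"mask contains labels {sorted(unknown)} absent from class_map "
                f"{sorted(self.class_map)}"
            )

    @property
    def shape(self):
        return self.labels.shape


@dataclass
class ViewImage:
    pixels: np.ndarray
    carcass_id: str
    view: str
    replicate: int = 1


@dataclass
class CarcassRecord:
    """Ground-truth weights (grams) for one carcass."""

    carcass_id: str
    total_g: float
    part_g: dict[str, float]
    clamped: list[str] = field(default_factory=list)


@dataclass
class SplitManifest:
    assignment: dict[str, str]

    def subset(self, name: str) -> list[str]:
        return sorted(k for k, v in self.assignment.items() if v == name)

    def validate_partition(self, ids) -> None:
        ids = set(ids)
        assigned = set(self.assignment)
        if assigned != ids:
            raise ValueError("split assignment does not cover the id set exactly")
        if not set(self.assignment.values()) <= {"train", "val", "test"}:
            raise ValueError("subset names must be train/val/test")


def read_labelme(json_text: str, class_map: dict[str, int],
                 canvas: tuple[int, int]) -> LabelMask:
    """Rasterize a Labelme annotation string onto an all-background canvas."""
    try:
        doc = json.loads(json_text)
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed Labelme JSON: {e}") from e
    h, w = canvas
    labels = np.zeros((h, w), dtype=np.int64)
    ys, xs = np.mgrid[0:h, 0:w]
    pts_x = xs.ravel() + 0.5
    pts_y = ys.ravel() + 0.5
    for shape in doc.get("shapes", []):
        name = shape["label"]
        if name not in class_map:
            raise ValueError(
                f"unknown label {name!r}; known labels: {sorted(class_map)}"
            )
        poly = Polygon(shape["points"])
        inside = contains_xy(poly, pts_x, pts_y).reshape(h, w)
        labels[inside] = class_map[name]
    inv = {v: k for k, v in class_map.items()}
    inv.setdefault(0, "background")
    return LabelMask(labels, inv)


def build_split(carcass_ids, ratios=(8, 1, 1), seed: int = 0) -> SplitManifest:
    """Seed-deterministic carcass-wise partition into train/val/test."""
    ids = list(carcass_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("carcass ids must be unique")
    if any(r <= 0 for r in ratios) or len(ratios) != 3:
        raise ValueError("ratios must be three positive numbers")
    total = sum(ratios)
    n = len(ids)
    n_val = int(np.floor(n * ratios[1] / total))
    n_test = int(np.floor(n * ratios[2] / total))
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(n)]
    assignment = {}
    for cid in order[:n_val]:
        assignment[cid] = "val"
    for cid in order[n_val : n_val + n_test]:
        assignment[cid] = "test"
    for cid in order[n_val + n_test :]:
        assignment[cid] = "train"
    manifest = SplitManifest(assignment)
    manifest.validate_partition(ids)
    return manifest


def write_mask(mask: LabelMask, path, palette: dict[int, tuple] | None = None) -> None:
    """Write a label mask as an indexed PNG with one palette color per label."""
    palette = palette or _DEFAULT_PALETTE
    colors = [palette.get(i) for i in sorted(palette)]
    if len(set(colors)) != len(colors):
        dupes = [c for c in set(colors) if colors.count(c) > 1]
        raise ValueError(f"palette collision: color(s) {dupes} used for two labels")
    missing = set(np.unique(mask.labels).tolist()) - set(palette)
    if missing:
        raise ValueError(f"labels {sorted(missing)} have no palette entry")
    img = Image.fromarray(mask.labels.astype(np.uint8), mode="P")
    flat = []
    for i in range(max(palette) + 1):
        flat.extend(palette.get(i, (0, 0, 0)))
    img.putpalette(flat)
    img.save(path, format="PNG")


def read_mask(path, class_map: dict[int, str] | None = None) -> LabelMask:
    img = Image.open(path)
    if img.mode != "P":
        raise ValueError(f"expected an indexed PNG, got mode {img.mode!r}")
    labels = np.asarray(img, dtype=np.int64)
    return LabelMask(labels, dict(class_map) if class_map else dict(CLASS_NAMES))


def write_image(pixels: np.ndarray, path) -> None:
    Image.fromarray(pixels.astype(np.uint8), mode="RGB").save(path, format="PNG")


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"), dtype=np.uint8)
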