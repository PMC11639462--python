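"""Synthetic surveillance-scene generator.

Emulates the structure of a wetland bird-surveillance dataset — five target
classes, dense and partially occluded small targets, large scale variation,
cluttered low-contrast backgrounds — without any photographic content.
Each class is a distinct colored shape (the light, low-saturation class
mimics pale swans against bright water); what matters for testing the
detector stack is the *box statistics* (density, scale, occlusion), which
are controlled, not photorealism.

Images are written as PNG, labels in YOLO text format (``class xc yc w h``,
normalized, one file per image), plus a YAML dataset config.  Pixel
coordinates are 0-based and boxes are half-open on the pixel grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .evalkit import GroundTruth
from .boxloss import BoundingBox

__all__ = [
    "SceneSpec", "DatasetSpec", "generate_scene", "generate_dataset",
    "split_dataset", "write_yolo_label", "DEFAULT_CLASS_NAMES",
]

log = logging.getLogger(__name__)

DEFAULT_CLASS_NAMES = [
    "white_crane", "white_fronted_goose", "white_stork", "common_crane",
    "tundra_swan",
]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene."""

    image_size: int = 640
    num_classes: int = 5
    objects_range: tuple = (3, 12)        # objects per image (inclusive)
    scale_range: tuple = (0.02, 0.35)     # object size as fraction of image
    occlusion_fraction: float = 0.3       # fraction of objects in overlapping pairs
    clutter: float = 0.6                  # background texture strength in [0,1]
    seed: int = 0

    def __post_init__(self):
        if self.objects_range[0] > self.objects_range[1] or self.objects_range[0] < 0:
            raise ValueError("invalid objects_range")
        if not (0 < self.scale_range[0] <= self.scale_range[1] <= 1):
            raise ValueError("invalid scale_range")
        if not 0 <= self.occlusion_fraction <= 1:
            raise ValueError("invalid occlusion_fraction")


@dataclass(frozen=True)
class DatasetSpec:
    total: int = 100
    ratios: tuple = (0.7, 0.2, 0.1)
    split_names: tuple = ("train", "val", "test")

    def __post_init__(self):
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if len(self.ratios) != len(self.split_names):
            raise ValueError("one ratio per split")


def split_dataset(n: int, ratios=(0.7, 0.2, 0.1)) -> tuple:
    """Partition ``n`` items: floor each share, hand leftovers to the later
    splits in order (second split first, then third, ...)."""
    ratios = np.asarray(ratios, dtype=float)
    ratios = ratios / ratios.sum()
    if n < len(ratios):
        raise ValueError(f"need at least {len(ratios)} items, got {n}")
    sizes = np.floor(ratios * n).astype(int)
    for k in range(1, len(sizes)):
        if sizes.sum() >= n:
            break
        sizes[k] += 1
    # any residue (can only occur with many splits) goes to the first
    sizes[0] += n - sizes.sum()
    return tuple(int(s) for s in sizes)


# ----------------------------------------------------------------- rendering
def _class_color(cls: int, num_classes: int, rng) -> np.ndarray:
    """Distinct hue per class; the last class is pale (low saturation)."""
    h = (cls / max(num_classes, 1)) % 1.0
    pale = cls == num_classes - 1
    s = 0.15 if pale else 0.75 + 0.15 * rng.random()
    v = 0.92 if pale else 0.55 + 0.3 * rng.random()
    i = int(h * 6) % 6
    f = h * 6 - int(h * 6)
    p, q, t = v * (1 - s), v * (1 - f * s), v * (1 - (1 - f) * s)
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.array(rgb) * 255.0


def _shape_mask(kind: int, h: int, w: int, rng) -> np.ndarray:
    """Boolean mask of the class shape on an h x w patch."""
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    u = (xx - cx) / max(w / 2.0, 1)
    v = (yy - cy) / max(h / 2.0, 1)
    kind = kind % 5
    if kind == 0:  # ellipse
        return u**2 + v**2 <= 1.0
    if kind == 1:  # triangle
        return (v >= -1.0) & (v <= 1.0) & (np.abs(u) <= (v + 1.0) / 2.0)
    if kind == 2:  # rectangle
        return (np.abs(u) <= 0.95) & (np.abs(v) <= 0.95)
    if kind == 3:  # plus / cross
        return (np.abs(u) <= 0.33) | (np.abs(v) <= 0.33)
    # crescent: full ellipse minus an offset ellipse
    full = u**2 + v**2 <= 1.0
    bite = (u - 0.45)**2 + (v - 0.25)**2 <= 0.72
    m = full & ~bite
    return m if m.any() else full


def _background(size: int, clutter: float, rng) -> np.ndarray:
    """Low-frequency colored texture plus speckle, scaled by ``clutter``."""
    base = np.array([90.0, 110.0, 100.0]) + rng.uniform(-30, 30, 3)
    img = np.ones((size, size, 3)) * base
    for cells in (4, 16):
        coarse = rng.uniform(-40, 40, (cells, cells, 3)) * clutter
        img += np.kron(coarse, np.ones((size // cells, size // cells, 1)))
    img += rng.normal(0.0, 12.0 * clutter, (size, size, 3))
    return img


def generate_scene(spec: SceneSpec, rng: np.random.Generator | None = None):
    """Render one scene.

    Returns ``(image, gts)`` where ``image`` is (H, W, 3) uint8 and ``gts``
    are :class:`~avidet.evalkit.GroundTruth` with normalized center-format
    boxes tight to the rendered extent and clipped to the image.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    S = spec.image_size
    img = _background(S, spec.clutter, rng)
    n_obj = int(rng.integers(spec.objects_range[0], spec.objects_range[1] + 1))
    n_pairs = int(round(spec.occlusion_fraction * n_obj / 2.0))

    gts: list = []
    placed: list = []  # (y0, x0, y1, x1) pixel extents

    def try_place(anchor=None):
        for _ in range(30):
            s = math.exp(rng.uniform(math.log(spec.scale_range[0]),
                                     math.log(spec.scale_range[1]))) * S
            aspect = math.exp(rng.normal(0.0, 0.25))
            w = max(3, int(round(s * aspect)))
            h = max(3, int(round(s / aspect)))
            if anchor is None:
                x0 = int(rng.integers(-w // 4, S - 3 * w // 4 + 1))
                y0 = int(rng.integers(-h // 4, S - 3 * h // 4 + 1))
            else:
                ay0, ax0, ay1, ax1 = anchor
                # constructive overlap: start inside the anchor's box
                x0 = int(rng.integers(ax0 - w // 2, ax1 - w // 2 + 1))
                y0 = int(rng.integers(ay0 - h // 2, ay1 - h // 2 + 1))
            cy0, cx0 = max(y0, 0), max(x0, 0)
            cy1, cx1 = min(y0 + h, S), min(x0 + w, S)
            if cy1 - cy0 < 3 or cx1 - cx0 < 3:
                continue
            if anchor is None:
                # keep un-occluded objects mostly separate
                ok = all(min(cy1, b[2]) - max(cy0, b[0]) <= 0.5 * (cy1 - cy0)
                         or min(cx1, b[3]) - max(cx0, b[1]) <= 0.5 * (cx1 - cx0)
                         for b in placed)
                if not ok:
                    continue
            cls = int(rng.integers(spec.num_classes))
            mask = _shape_mask(cls, h, w, rng)[cy0 - y0:cy1 - y0, cx0 - x0:cx1 - x0]
            if not mask.any():
                continue
            color = _class_color(cls, spec.num_classes, rng)
            color = color + rng.normal(0, 10, 3)
            patch = img[cy0:cy1, cx0:cx1]
            patch[mask] = color
            ys, xs = np.nonzero(mask)
            ty0, ty1 = cy0 + ys.min(), cy0 + ys.max() + 1
            tx0, tx1 = cx0 + xs.min(), cx0 + xs.max() + 1
            placed.append((ty0, tx0, ty1, tx1))
            box = BoundingBox(((tx0 + tx1) / 2) / S, ((ty0 + ty1) / 2) / S,
                              (tx1 - tx0) / S, (ty1 - ty0) / S)
            gts.append(GroundTruth("", cls, box))
            return (ty0, tx0, ty1, tx1)
        return None

    made = 0
    for _ in range(n_pairs):
        a = try_place()
        if a is None:
            continue
        made += 1
        if try_place(anchor=a) is not None:
            made += 1
    while made < n_obj:
        if try_place() is None:
            log.warning("placement failed; emitting %d of %d objects", made, n_obj)
            break
        made += 1

    img = np.clip(img, 0, 255).astype(np.uint8)
    return img, gts


def write_yolo_label(path, gts):
    lines = [f"{g.class_id} {g.box.xc:.6f} {g.box.yc:.6f} "
             f"{g.box.w:.6f} {g.box.h:.6f}" for g in gts]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def generate_dataset(root, dspec: DatasetSpec, sspec: SceneSpec,
                     class_names=None) -> Path:
    """Write a split image/label tree plus a dataset YAML; returns the YAML
    path.  Scene i is generated from ``sspec.seed + i`` so the dataset is
    reproducible and images are independent."""
    root = Path(root)
    names = list(class_names or DEFAULT_CLASS_NAMES)[:sspec.num_classes]
    while len(names) < sspec.num_classes:
        names.append(f"class{len(names)}")
    sizes = split_dataset(dspec.total, dspec.ratios)
    order = np.random.default_rng(sspec.seed).permutation(dspec.total)
    bounds = np.cumsum((0,) + sizes)
    cfg = {"names": {i: n for i, n in enumerate(names)}, "nc": sspec.num_classes}
    for k, split in enumerate(dspec.split_names):
        (root / split / "images").mkdir(parents=True, exist_ok=True)
        (root / split / "labels").mkdir(parents=True, exist_ok=True)
        cfg[split] = str(root / split / "images")
        for idx in order[bounds[k]:bounds[k + 1]]:
            stem = f"img_{idx:05d}"
            rng = np.random.default_rng(sspec.seed + int(idx))
            img, gts = generate_scene(sspec, rng)
            Image.fromarray(img).save(root / split / "images" / f"{stem}.png")
            write_yolo_label(root / split / "labels" / f"{stem}.txt", gts)
    cfg_path = root / "data.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return cfg_path
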