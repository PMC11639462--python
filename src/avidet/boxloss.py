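"""Bounding-box geometry and the IoU-based regression-loss family.

The family implemented here:

* ``iou`` — plain intersection over union;
* ``ciou_loss`` — complete IoU (the stock YOLOv8 box loss; ablation baseline);
* ``shape_iou_loss`` — IoU loss whose center-distance and shape-cost terms
  are weighted by the ground-truth box's own aspect (weights ``ww``/``hh``
  built from ``w_gt^scale`` and ``h_gt^scale``, always summing to 2), with
  the shape cost ``(1 - exp(-|dw|/max))**theta``;
* ``inner_iou`` — IoU of auxiliary boxes obtained by scaling each box's
  width/height by ``ratio`` about its own center (0.5 shrinks, 1.5 grows);
* ``inner_shape_iou_loss`` — Shape-IoU with the plain-IoU term replaced by
  the inner variant: ``L_shape + IoU - IoU_inner``.

Conventions: ``c^2`` is the squared diagonal of the smallest axis-aligned
box enclosing both boxes (the standard DIoU-family normalizer); the
distance term pairs ``hh`` with the x-offset and ``ww`` with the y-offset;
zero-area overlap yields IoU 0, not an error.

Two surfaces are provided: scalar functions on :class:`BoundingBox` (used
by tests and the evaluation tools, computed in float64) and batched tensor
functions (suffix ``_t``, operating on ``(..., 4)`` corner-format autodiff
tensors) that the training loop differentiates through.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, maximum, minimum, stack

__all__ = [
    "BoundingBox", "ShapeLossParams", "InnerParams", "LossBreakdown",
    "InvalidBoxError", "ParameterError",
    "iou", "inner_iou", "ciou_loss", "shape_iou_loss", "inner_shape_iou_loss",
    "iou_t", "inner_iou_t", "ciou_loss_t", "shape_iou_loss_t",
    "inner_shape_iou_loss_t", "make_box_loss", "xywh_to_xyxy_t",
]


class InvalidBoxError(ValueError):
    pass


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in center form; width and height must be positive."""

    xc: float
    yc: float
    w: float
    h: float

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise InvalidBoxError(f"non-positive box size w={self.w}, h={self.h}")

    @classmethod
    def from_corners(cls, x1, y1, x2, y2) -> "BoundingBox":
        return cls((x1 + x2) / 2.0, (y1 + y2) / 2.0, x2 - x1, y2 - y1)

    @property
    def corners(self) -> tuple:
        return (self.xc - self.w / 2.0, self.yc - self.h / 2.0,
                self.xc + self.w / 2.0, self.yc + self.h / 2.0)

    @property
    def area(self) -> float:
        return self.w * self.h

    def as_array(self) -> np.ndarray:
        return np.array([self.xc, self.yc, self.w, self.h], dtype=np.float64)


@dataclass(frozen=True)
class ShapeLossParams:
    """``scale``: size-sensitivity exponent of the ww/hh weights (0 makes
    them both 1); ``theta``: shape-cost power, typically 4."""

    scale: float = 0.0
    theta: float = 4.0

    def __post_init__(self):
        if not self.theta > 0:
            raise ParameterError(f"theta must be positive, got {self.theta}")
        if self.scale < 0:
            raise ParameterError(f"scale must be nonnegative, got {self.scale}")


@dataclass(frozen=True)
class InnerParams:
    """``ratio`` scales the auxiliary boxes; the useful range is [0.5, 1.5]."""

    ratio: float = 1.0

    def __post_init__(self):
        if not 0.5 <= self.ratio <= 1.5:
            raise ParameterError(f"ratio must lie in [0.5, 1.5], got {self.ratio}")


@dataclass(frozen=True)
class LossBreakdown:
    iou: float
    inner_iou: float
    distance_shape: float
    omega_shape: float
    total: float


# --------------------------------------------------------------- tensor core
def xywh_to_xyxy_t(b: Tensor) -> Tensor:
    xc, yc, w, h = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return stack([xc - w * 0.5, yc - h * 0.5, xc + w * 0.5, yc + h * 0.5], axis=-1)


def _split(b: Tensor):
    return b[..., 0], b[..., 1], b[..., 2], b[..., 3]


def iou_t(p: Tensor, g: Tensor, eps: float = 1e-9) -> Tensor:
    """IoU of corner-format boxes, elementwise over the leading axes."""
    px1, py1, px2, py2 = _split(p)
    gx1, gy1, gx2, gy2 = _split(g)
    iw = (minimum(px2, gx2) - maximum(px1, gx1)).clamp(0.0)
    ih = (minimum(py2, gy2) - maximum(py1, gy1)).clamp(0.0)
    inter = iw * ih
    union = (px2 - px1) * (py2 - py1) + (gx2 - gx1) * (gy2 - gy1) - inter
    return inter / (union + eps)


def inner_iou_t(p: Tensor, g: Tensor, ratio: float = 1.0, eps: float = 1e-9) -> Tensor:
    """IoU of the ratio-scaled auxiliary boxes (scaled about each center).

    Auxiliary corners ``center -/+ ratio*size/2`` are formed by corner
    interpolation (``x1*(1+r)/2 + x2*(1-r)/2``), which is algebraically the
    same and makes ratio = 1 reproduce the original corners exactly, so the
    inner IoU then equals the plain IoU bitwise.
    """
    a, b = (1.0 + ratio) * 0.5, (1.0 - ratio) * 0.5

    def aux(t):
        x1, y1, x2, y2 = _split(t)
        return stack([x1 * a + x2 * b, y1 * a + y2 * b,
                      x2 * a + x1 * b, y2 * a + y1 * b], axis=-1)

    return iou_t(aux(p), aux(g), eps)


def _enclosing_diag_sq(p: Tensor, g: Tensor) -> Tensor:
    px1, py1, px2, py2 = _split(p)
    gx1, gy1, gx2, gy2 = _split(g)
    cw = maximum(px2, gx2) - minimum(px1, gx1)
    ch = maximum(py2, gy2) - minimum(py1, gy1)
    return cw * cw + ch * ch


def shape_iou_terms_t(p: Tensor, g: Tensor, scale: float = 0.0,
                      theta: float = 4.0, eps: float = 1e-9) -> dict:
    """Per-pair Shape-IoU ingredients as tensors."""
    px1, py1, px2, py2 = _split(p)
    gx1, gy1, gx2, gy2 = _split(g)
    pw, ph = px2 - px1, py2 - py1
    gw, gh = gx2 - gx1, gy2 - gy1
    pcx, pcy = (px1 + px2) * 0.5, (py1 + py2) * 0.5
    gcx, gcy = (gx1 + gx2) * 0.5, (gy1 + gy2) * 0.5

    gws, ghs = gw ** scale, gh ** scale
    den = gws + ghs + eps
    ww = 2.0 * gws / den
    hh = 2.0 * ghs / den

    c2 = _enclosing_diag_sq(p, g) + eps
    dist = (hh * (pcx - gcx) ** 2 + ww * (pcy - gcy) ** 2) / c2

    omega_w = (1.0 - (-( (pw - gw).abs() / maximum(pw, gw) )).exp()) ** theta
    omega_h = (1.0 - (-( (ph - gh).abs() / maximum(ph, gh) )).exp()) ** theta
    omega = omega_w + omega_h

    return {"iou": iou_t(p, g, eps), "distance": dist, "omega": omega}


def shape_iou_loss_t(p: Tensor, g: Tensor, scale: float = 0.0,
                     theta: float = 4.0) -> Tensor:
    t = shape_iou_terms_t(p, g, scale, theta)
    return 1.0 - t["iou"] + t["distance"] + 0.5 * t["omega"]


def inner_shape_iou_loss_t(p: Tensor, g: Tensor, scale: float = 0.0,
                           theta: float = 4.0, ratio: float = 1.0) -> Tensor:
    t = shape_iou_terms_t(p, g, scale, theta)
    l_shape = 1.0 - t["iou"] + t["distance"] + 0.5 * t["omega"]
    # grouping (IoU - IoU_inner) keeps ratio = 1 an exact no-op
    return l_shape + (t["iou"] - inner_iou_t(p, g, ratio))


def ciou_loss_t(p: Tensor, g: Tensor, eps: float = 1e-9) -> Tensor:
    px1, py1, px2, py2 = _split(p)
    gx1, gy1, gx2, gy2 = _split(g)
    pw, ph = px2 - px1, py2 - py1
    gw, gh = gx2 - gx1, gy2 - gy1
    pcx, pcy = (px1 + px2) * 0.5, (py1 + py2) * 0.5
    gcx, gcy = (gx1 + gx2) * 0.5, (gy1 + gy2) * 0.5
    i = iou_t(p, g, eps)
    rho2 = (pcx - gcx) ** 2 + (pcy - gcy) ** 2
    c2 = _enclosing_diag_sq(p, g) + eps
    v = (4.0 / np.pi**2) * ((gw / gh).arctan() - (pw / ph).arctan()) ** 2
    alpha = v / (1.0 - i + v + 1e-12)  # aspect-ratio trade-off weight
    return 1.0 - i + rho2 / c2 + alpha * v


# --------------------------------------------------------------- scalar API
def _pair(a: BoundingBox, b: BoundingBox):
    pa = Tensor(np.array(a.corners, dtype=np.float64))
    pb = Tensor(np.array(b.corners, dtype=np.float64))
    return pa, pb


def iou(a: BoundingBox, b: BoundingBox) -> float:
    pa, pb = _pair(a, b)
    return float(iou_t(pa, pb, eps=0.0).data)


def inner_iou(pred: BoundingBox, gt: BoundingBox,
              p: InnerParams = InnerParams()) -> float:
    pa, pb = _pair(pred, gt)
    return float(inner_iou_t(pa, pb, p.ratio, eps=0.0).data)


def shape_iou_loss(pred: BoundingBox, gt: BoundingBox,
                   p: ShapeLossParams = ShapeLossParams()) -> LossBreakdown:
    pa, pb = _pair(pred, gt)
    t = shape_iou_terms_t(pa, pb, p.scale, p.theta, eps=0.0)
    i = float(t["iou"].data)
    dist = float(t["distance"].data)
    om = float(t["omega"].data)
    return LossBreakdown(iou=i, inner_iou=i, distance_shape=dist,
                         omega_shape=om, total=1.0 - i + dist + 0.5 * om)


def inner_shape_iou_loss(pred: BoundingBox, gt: BoundingBox,
                         sp: ShapeLossParams = ShapeLossParams(),
                         ip: InnerParams = InnerParams()) -> LossBreakdown:
    base = shape_iou_loss(pred, gt, sp)
    ii = inner_iou(pred, gt, ip)
    return LossBreakdown(iou=base.iou, inner_iou=ii,
                         distance_shape=base.distance_shape,
                         omega_shape=base.omega_shape,
                         total=base.total + (base.iou - ii))


def ciou_loss(pred: BoundingBox, gt: BoundingBox) -> LossBreakdown:
    pa, pb = _pair(pred, gt)
    total = float(ciou_loss_t(pa, pb, eps=0.0).data)
    i = iou(pred, gt)
    return LossBreakdown(iou=i, inner_iou=i, distance_shape=total - (1.0 - i),
                         omega_shape=0.0, total=total)


def make_box_loss(spec: dict | None):
    """Build a batched box-loss callable ``f(pred_xyxy, gt_xyxy) -> Tensor``
    from a config mapping like ``{"name": "inner_shape_iou", "ratio": 1.0,
    "scale": 0.0, "theta": 4.0}``."""
    spec = dict(spec or {})
    name = spec.pop("name", "ciou")
    scale = float(spec.pop("scale", 0.0))
    theta = float(spec.pop("theta", 4.0))
    ratio = float(spec.pop("ratio", 1.0))
    ShapeLossParams(scale=scale, theta=theta)
    InnerParams(ratio=ratio)
    if spec:
        raise ParameterError(f"unknown box-loss options {sorted(spec)}")
    if name == "ciou":
        return ciou_loss_t
    if name == "shape_iou":
        return lambda p, g: shape_iou_loss_t(p, g, scale, theta)
    if name == "inner_iou":
        return lambda p, g: 1.0 - inner_iou_t(p, g, ratio)
    if name == "inner_shape_iou":
        return lambda p, g: inner_shape_iou_loss_t(p, g, scale, theta, ratio)
    raise ParameterError(f"unknown box loss {name!r}")
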