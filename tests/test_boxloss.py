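"""Box geometry and the IoU / CIoU / Shape-IoU / Inner-IoU loss family."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from avidet.boxloss import (BoundingBox, InnerParams, InvalidBoxError,
                            ParameterError, ShapeLossParams, ciou_loss,
                            inner_iou, inner_shape_iou_loss, iou,
                            make_box_loss, shape_iou_loss)
from avidet.boxloss import (ciou_loss_t, inner_iou_t, inner_shape_iou_loss_t,
                            iou_t, shape_iou_loss_t, xywh_to_xyxy_t)
from avidet.nn import Tensor
from conftest import random_box_pair

B = BoundingBox.from_corners


# ------------------------------------------------------------------ geometry
def test_corner_center_roundtrip():
    b = BoundingBox(1.25, -3.5, 2.0, 0.75)
    rb = B(*b.corners)
    for f in ("xc", "yc", "w", "h"):
        assert abs(getattr(rb, f) - getattr(b, f)) < 1e-9


@pytest.mark.parametrize("w,h", [(0, 1), (1, 0), (-2, 3)])
def test_invalid_box_rejected(w, h):
    with pytest.raises(InvalidBoxError):
        BoundingBox(0, 0, w, h)


@pytest.mark.parametrize("a,b,expected", [
    (B(0, 0, 2, 2), B(0, 0, 2, 2), 1.0),           # identity
    (B(0, 0, 2, 2), B(3, 3, 4, 4), 0.0),           # disjoint
    (B(0, 0, 2, 2), B(1, 1, 3, 3), 1 / 7),         # inter 1, union 7
    (B(0, 0, 2, 2), B(2, 0, 4, 2), 0.0),           # touching edge: zero area
])
def test_iou_values(a, b, expected):
    assert iou(a, b) == pytest.approx(expected, abs=1e-12)


def test_iou_rasterization_oracle(rng):
    """Analytic IoU agrees with a pixel-rasterization estimate."""
    for _ in range(100):
        a, b = random_box_pair(rng, near=bool(rng.integers(2)))
        x1 = min(a.corners[0], b.corners[0])
        y1 = min(a.corners[1], b.corners[1])
        x2 = max(a.corners[2], b.corners[2])
        y2 = max(a.corners[3], b.corners[3])
        n = 2000
        xs = (x1 + (np.arange(n) + 0.5) * (x2 - x1) / n)[None, :]
        ys = (y1 + (np.arange(n) + 0.5) * (y2 - y1) / n)[:, None]

        def inside(box):
            c = box.corners
            return (xs >= c[0]) & (xs <= c[2]) & (ys >= c[1]) & (ys <= c[3])

        ma, mb = inside(a), inside(b)
        union = (ma | mb).sum()
        raster = (ma & mb).sum() / union if union else 0.0
        assert abs(raster - iou(a, b)) < 2e-3


# ---------------------------------------------------------------- inner IoU
def test_inner_iou_ratio_one_reduces_to_iou(rng):
    for _ in range(50):
        a, b = random_box_pair(rng, near=True)
        assert inner_iou(a, b, InnerParams(1.0)) == pytest.approx(iou(a, b), abs=1e-12)


@pytest.mark.parametrize("ratio,expected", [
    (0.5, 0.0),            # shrunk boxes touch at a point
    (1.5, 2 / 7),          # grown boxes: inter 4, union 14
])
def test_inner_iou_scaled_examples(ratio, expected):
    a, b = B(0, 0, 2, 2), B(1, 1, 3, 3)
    assert inner_iou(a, b, InnerParams(ratio)) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("ratio", [0.49, 1.51, -1.0])
def test_inner_ratio_range_enforced(ratio):
    with pytest.raises(ParameterError):
        InnerParams(ratio)


# ------------------------------------------------------------ Shape-IoU loss
@pytest.mark.parametrize("pred,gt,params,expected", [
    (BoundingBox(0, 0, 3, 2), BoundingBox(0, 0, 3, 2), ShapeLossParams(), 0.0),
    (BoundingBox(1, 0, 4, 2), BoundingBox(0, 0, 4, 2), ShapeLossParams(1, 4),
     0.6 + (2 / 3) / 29 - 0.2),                        # = 0.42299
    (BoundingBox(0, 0, 2, 2), BoundingBox(0, 0, 4, 2), ShapeLossParams(0, 4),
     0.5 + 0.5 * (1 - math.exp(-0.5)) ** 4),           # = 0.51198
])
def test_shape_iou_worked_examples(pred, gt, params, expected):
    out = shape_iou_loss(pred, gt, params)
    assert out.total == pytest.approx(expected, abs=1e-5)
    # total is reproducible from the reported components
    assert out.total == pytest.approx(
        1 - out.iou + out.distance_shape + 0.5 * out.omega_shape, abs=1e-12)


@given(w=st.floats(0.1, 50), h=st.floats(0.1, 50), scale=st.floats(0, 3))
@settings(max_examples=200, deadline=None)
def test_shape_weights_sum_to_two(w, h, scale):
    """ww + hh = 2 for any ground-truth box and any scale exponent."""
    ws, hs = w**scale, h**scale
    ww, hh = 2 * ws / (ws + hs), 2 * hs / (ws + hs)
    gt = BoundingBox(0, 0, w, h)
    out = shape_iou_loss(BoundingBox(0.5, 0.2, w, h), gt, ShapeLossParams(scale))
    # reconstruct the weights from the distance term: dist = (hh*dx^2+ww*dy^2)/c2
    assert ww + hh == pytest.approx(2.0, abs=1e-9)
    assert np.isfinite(out.total)


# ------------------------------------------------------- Inner-ShapeIoU loss
def test_inner_shape_worked_example():
    out = inner_shape_iou_loss(B(0, 0, 2, 2), B(1, 1, 3, 3),
                               ShapeLossParams(0, 4), InnerParams(0.5))
    assert out.total == pytest.approx(10 / 9, abs=1e-5)


def test_inner_shape_ratio_one_equals_shape(rng):
    for _ in range(50):
        a, b = random_box_pair(rng, near=True)
        sp = ShapeLossParams(scale=float(rng.uniform(0, 2)))
        s = shape_iou_loss(a, b, sp).total
        i = inner_shape_iou_loss(a, b, sp, InnerParams(1.0)).total
        assert i == pytest.approx(s, abs=0.0)  # exact


@pytest.mark.parametrize("ratio", [0.5, 0.8, 1.0, 1.3, 1.5])
def test_all_losses_zero_iff_identical(ratio, rng):
    b = BoundingBox(0.3, -1.2, 2.5, 1.1)
    assert inner_shape_iou_loss(b, b, ip=InnerParams(ratio)).total == pytest.approx(0, abs=1e-12)
    assert shape_iou_loss(b, b).total == 0
    assert ciou_loss(b, b).total == pytest.approx(0, abs=1e-9)
    # and nonzero whenever pred != gt
    a, g = random_box_pair(rng, near=True)
    if a != g:
        assert inner_shape_iou_loss(a, g, ip=InnerParams(ratio)).total > 0


# ------------------------------------------------------------------- CIoU
def test_ciou_examples():
    assert ciou_loss(B(0, 0, 2, 2), B(0, 0, 2, 2)).total == pytest.approx(0, abs=1e-9)
    # same center, same aspect: exactly 1 - IoU
    a, b = BoundingBox(0, 0, 2, 2), BoundingBox(0, 0, 4, 4)
    assert ciou_loss(a, b).total == pytest.approx(1 - iou(a, b), abs=1e-9)
    out = ciou_loss(BoundingBox(1, 0, 2, 2), BoundingBox(0, 0, 2, 2))
    assert out.total == pytest.approx(1 - 1 / 3 + 1 / 13, abs=1e-5)


# ------------------------------------------------- monotonicity & gradients
def test_losses_monotone_along_center_line():
    """Translating pred toward gt along the center line never raises a loss."""
    gt = BoundingBox(0, 0, 3, 2)
    offsets = np.linspace(3.0, 0.0, 25)
    for fn in (
        lambda p: 1 - iou(p, gt),
        lambda p: 1 - inner_iou(p, gt, InnerParams(1.2)),
        lambda p: shape_iou_loss(p, gt).total,
        lambda p: inner_shape_iou_loss(p, gt, ip=InnerParams(0.8)).total,
        lambda p: ciou_loss(p, gt).total,
    ):
        vals = [fn(BoundingBox(d * 0.6, d * 0.8, 3, 2)) for d in offsets]
        assert all(b <= a + 1e-9 for a, b in zip(vals, vals[1:]))


LOSS_T = {
    "iou": lambda p, g: 1.0 - iou_t(p, g),
    "inner_iou_0.7": lambda p, g: 1.0 - inner_iou_t(p, g, 0.7),
    "shape": lambda p, g: shape_iou_loss_t(p, g, scale=0.5),
    "inner_shape_1.3": lambda p, g: inner_shape_iou_loss_t(p, g, 0.5, 4.0, 1.3),
    "ciou": ciou_loss_t,
}


@pytest.mark.parametrize("name", sorted(LOSS_T))
def test_autodiff_matches_numerical_gradients(name, rng):
    """Central differences vs backprop w.r.t. (xc, yc, w, h), 100 pairs."""
    fn = LOSS_T[name]
    checked = 0
    while checked < 100:
        a, g = random_box_pair(rng, near=True)
        if iou(a, g) < 0.05:
            continue  # keep away from non-differentiable disjoint corner
        p = Tensor(a.as_array(), requires_grad=True)
        gt = Tensor(xywh_to_xyxy_t(Tensor(g.as_array())).data)

        def loss():
            return fn(xywh_to_xyxy_t(p), gt)

        out = loss()
        out.backward()
        grad = p.grad.copy()
        eps = 1e-6
        for k in range(4):
            p.data[k] += eps
            lp = loss().item()
            p.data[k] -= 2 * eps
            lm = loss().item()
            p.data[k] += eps
            num = (lp - lm) / (2 * eps)
            denom = max(abs(num), abs(grad[k]), 1e-3)
            assert abs(num - grad[k]) / denom < 1e-4, (name, k, num, grad[k])
        checked += 1


# ------------------------------------------------------------- config plumbing
def test_make_box_loss_selection():
    f = make_box_loss({"name": "inner_shape_iou", "ratio": 1.0,
                       "scale": 0.0, "theta": 4.0})
    g = make_box_loss({"name": "shape_iou"})
    p = Tensor(np.array([0.0, 0.0, 2.0, 2.0]))
    q = Tensor(np.array([0.5, 0.5, 2.5, 2.5]))
    assert f(p, q).item() == pytest.approx(g(p, q).item(), abs=1e-12)
    with pytest.raises(ParameterError):
        make_box_loss({"name": "giou"})
    with pytest.raises(ParameterError):
        make_box_loss({"name": "inner_iou", "ratio": 2.0})
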