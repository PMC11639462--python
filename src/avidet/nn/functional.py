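"""Convolution, pooling and resampling primitives with hand-written backward
passes, plus the FLOP-profiling hook used for architecture cost accounting.

Convolution is computed by an explicit tap loop + batched matmul (one BLAS
call per layer); the backward pass mirrors it with a scatter loop.  The
profiler counts 2 x multiply-accumulate per convolution/affine weight
application and ignores pooling, normalization and activations.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor

__all__ = [
    "conv2d", "avg_pool2d", "max_pool2d", "upsample_nearest", "pixel_shuffle",
    "pad2d", "grid_sample", "interpolate_bilinear", "linear", "flop_counter",
]

# --------------------------------------------------------------- FLOP profile
_FLOPS: list = []  # stack of active counters


class flop_counter:
    """Context manager accumulating 2xMAC FLOPs of conv/affine layers."""

    def __init__(self):
        self.flops = 0

    def __enter__(self):
        _FLOPS.append(self)
        return self

    def __exit__(self, *exc):
        _FLOPS.remove(self)
        return False


def _count(macs: int):
    for c in _FLOPS:
        c.flops += 2 * macs


# ---------------------------------------------------------------- convolution
def conv2d(x, w, b=None, stride: int = 1, padding: int = 0, groups: int = 1):
    """2-D cross-correlation. ``x``: (N,C,H,W); ``w``: (Co, C/groups, kh, kw)."""
    x, w = as_tensor(x), as_tensor(w)
    N, C, H, W = x.shape
    Co, Cig, kh, kw = w.shape
    g = groups
    assert C == Cig * g and Co % g == 0, "channel/group mismatch"
    s, p = stride, padding
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data

    if kh == kw == 1 and s == 1:
        cols = xp.reshape(N, g, Cig, Ho * Wo)
        ck = 1
    else:
        ck = kh * kw
        cols = np.empty((N, C, ck, Ho, Wo), dtype=x.dtype)
        for i in range(kh):
            for j in range(kw):
                cols[:, :, i * kw + j] = xp[:, :, i:i + s * Ho:s, j:j + s * Wo:s]
        cols = cols.reshape(N, g, Cig * ck, Ho * Wo)
    wmat = w.data.reshape(g, Co // g, Cig * ck)
    out = np.matmul(wmat, cols)  # (N, g, Co/g, Ho*Wo)
    out = out.reshape(N, Co, Ho, Wo)
    _count(Cig * ck * Co * Ho * Wo * N)
    if b is not None:
        bt = as_tensor(b)
        out = out + bt.data.reshape(1, Co, 1, 1)
    else:
        bt = None

    def backward(gout):
        gmat = gout.reshape(N, g, Co // g, Ho * Wo)
        if w.requires_grad:
            dw = np.matmul(gmat, np.swapaxes(cols, -1, -2)).sum(axis=0)
            w._accum(dw.reshape(w.shape))
        if bt is not None and bt.requires_grad:
            bt._accum(gout.sum(axis=(0, 2, 3)).reshape(bt.shape))
        if x.requires_grad:
            dcols = np.matmul(np.swapaxes(wmat, -1, -2), gmat)  # (N,g,Cig*ck,HoWo)
            if ck == 1:
                dxp = dcols.reshape(N, C, Ho, Wo)
                x._accum(dxp if p == 0 else dxp)  # p always 0 on this path
                return
            dcols = dcols.reshape(N, C, ck, Ho, Wo)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += dcols[:, :, i * kw + j]
            x._accum(dxp[:, :, p:p + H, p:p + W] if p else dxp)

    parents = (x, w) if bt is None else (x, w, bt)
    return Tensor._make(out.copy() if b is not None else out, parents, backward)


def linear(x, w, b=None):
    """Affine map on the last axis. ``w``: (out, in)."""
    x, w = as_tensor(x), as_tensor(w)
    out = x @ w.transpose(*range(w.ndim - 2), w.ndim - 1, w.ndim - 2)
    _count(x.size // x.shape[-1] * w.shape[0] * w.shape[1])
    if b is not None:
        out = out + as_tensor(b)
    return out


# -------------------------------------------------------------------- pooling
def avg_pool2d(x, k: int, stride: int | None = None, padding: int = 0):
    x = as_tensor(x)
    s = stride or k
    N, C, H, W = x.shape
    p = padding
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    acc = np.zeros((N, C, Ho, Wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            acc += xp[:, :, i:i + s * Ho:s, j:j + s * Wo:s]
    acc /= k * k

    def backward(g):
        dxp = np.zeros_like(xp)
        gk = g / (k * k)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += gk
        x._accum(dxp[:, :, p:p + H, p:p + W] if p else dxp)

    return Tensor._make(acc, (x,), backward)


def max_pool2d(x, k: int, stride: int | None = None, padding: int = 0):
    x = as_tensor(x)
    s = stride or k
    N, C, H, W = x.shape
    p = padding
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1
    if p:
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf)
    else:
        xp = x.data
    best = np.full((N, C, Ho, Wo), -np.inf, dtype=x.dtype)
    arg = np.zeros((N, C, Ho, Wo), dtype=np.int16)
    for i in range(k):
        for j in range(k):
            tap = xp[:, :, i:i + s * Ho:s, j:j + s * Wo:s]
            sel = tap > best
            best = np.where(sel, tap, best)
            arg[sel] = i * k + j

    def backward(g):
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                mask = arg == (i * k + j)
                dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += g * mask
        x._accum(dxp[:, :, p:p + H, p:p + W] if p else dxp)

    return Tensor._make(best, (x,), backward)


# ----------------------------------------------------------------- resampling
def upsample_nearest(x, factor: int):
    x = as_tensor(x)
    N, C, H, W = x.shape
    r = factor
    out = x.data.repeat(r, axis=2).repeat(r, axis=3)

    def backward(g):
        gg = g.reshape(N, C, H, r, W, r).sum(axis=(3, 5))
        x._accum(gg)

    return Tensor._make(out, (x,), backward)


def pixel_shuffle(x: Tensor, r: int) -> Tensor:
    """(N, C*r*r, H, W) -> (N, C, r*H, r*W); pure reshape/transpose."""
    N, Cr2, H, W = x.shape
    C = Cr2 // (r * r)
    return (x.reshape(N, C, r, r, H, W)
             .transpose(0, 1, 4, 2, 5, 3)
             .reshape(N, C, H * r, W * r))


def pad2d(x, p: int, mode: str = "constant"):
    """Pad the two trailing axes by ``p`` on each side."""
    x = as_tensor(x)
    if p == 0:
        return x
    if mode == "constant":
        N, C, H, W = x.shape
        out = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))

        def backward(g):
            x._accum(g[:, :, p:p + H, p:p + W])

        return Tensor._make(out, (x,), backward)
    if mode == "reflect":
        H, W = x.shape[-2:]
        ih = np.abs(np.arange(-p, H + p))
        ih = np.where(ih >= H, 2 * (H - 1) - ih, ih)
        iw = np.abs(np.arange(-p, W + p))
        iw = np.where(iw >= W, 2 * (W - 1) - iw, iw)
        return x[:, :, ih[:, None], iw[None, :]]
    raise ValueError(f"unknown pad mode {mode!r}")


def grid_sample(x, px, py):
    """Grouped bilinear sampling.

    ``x``: (N, C, H, W); ``px``/``py``: (N, G, Ho, Wo) sample positions in
    input pixel coordinates (0 .. W-1 / H-1), one grid per channel group.
    Coordinates are clamped to the border.  Differentiable in ``x`` and in
    the sampling positions.
    """
    x, px, py = as_tensor(x), as_tensor(px), as_tensor(py)
    N, C, H, W = x.shape
    _, G, Ho, Wo = px.shape
    Cg = C // G
    cx = np.clip(px.data, 0.0, W - 1.0)
    cy = np.clip(py.data, 0.0, H - 1.0)
    x0 = np.minimum(np.floor(cx), W - 2).astype(np.int64) if W > 1 else np.zeros_like(cx, dtype=np.int64)
    y0 = np.minimum(np.floor(cy), H - 2).astype(np.int64) if H > 1 else np.zeros_like(cy, dtype=np.int64)
    wx = cx - x0
    wy = cy - y0
    xf = x.data.reshape(N, G, Cg, H * W)
    P = Ho * Wo

    def gather(yy, xx):
        idx = (yy * W + xx).reshape(N, G, 1, P)
        idx = np.broadcast_to(idx, (N, G, Cg, P))
        return np.take_along_axis(xf, idx, axis=3)

    x1 = np.minimum(x0 + 1, W - 1)
    y1 = np.minimum(y0 + 1, H - 1)
    v00, v01 = gather(y0, x0), gather(y0, x1)
    v10, v11 = gather(y1, x0), gather(y1, x1)
    wxf = wx.reshape(N, G, 1, P)
    wyf = wy.reshape(N, G, 1, P)
    out = ((1 - wyf) * ((1 - wxf) * v00 + wxf * v01)
           + wyf * ((1 - wxf) * v10 + wxf * v11))
    out = out.reshape(N, C, Ho, Wo).astype(x.dtype)

    def backward(g):
        gf = g.reshape(N, G, Cg, P)
        if x.requires_grad:
            dxf = np.zeros_like(xf)
            for yy, xx, wgt in (
                (y0, x0, (1 - wyf) * (1 - wxf)),
                (y0, x1, (1 - wyf) * wxf),
                (y1, x0, wyf * (1 - wxf)),
                (y1, x1, wyf * wxf),
            ):
                idx = np.broadcast_to((yy * W + xx).reshape(N, G, 1, P), (N, G, Cg, P))
                np.add.at(dxf, (np.arange(N)[:, None, None, None],
                                np.arange(G)[None, :, None, None],
                                np.arange(Cg)[None, None, :, None],
                                idx), gf * wgt)
            x._accum(dxf.reshape(x.shape))
        if px.requires_grad or py.requires_grad:
            dvdx = ((1 - wyf) * (v01 - v00) + wyf * (v11 - v10))
            dvdy = ((1 - wxf) * (v10 - v00) + wxf * (v11 - v01))
            in_x = ((px.data > 0) & (px.data < W - 1)).reshape(N, G, 1, P)
            in_y = ((py.data > 0) & (py.data < H - 1)).reshape(N, G, 1, P)
            if px.requires_grad:
                px._accum(((gf * dvdx * in_x).sum(axis=2)).reshape(px.shape))
            if py.requires_grad:
                py._accum(((gf * dvdy * in_y).sum(axis=2)).reshape(py.shape))

    return Tensor._make(out, (x, px, py), backward)


def interpolate_bilinear(x, factor: int):
    """Plain bilinear upsampling by an integer factor (half-pixel centers)."""
    x = as_tensor(x)
    N, C, H, W = x.shape
    r = factor
    ox = (np.arange(W * r) + 0.5) / r - 0.5
    oy = (np.arange(H * r) + 0.5) / r - 0.5
    px = np.broadcast_to(ox[None, None, None, :], (N, 1, H * r, W * r))
    py = np.broadcast_to(oy[None, None, :, None], (N, 1, H * r, W * r))
    return grid_sample(x, Tensor(px.copy()), Tensor(py.copy()))
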