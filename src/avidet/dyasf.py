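"""DyASF-P2 multi-scale feature fusion.

The neck combines four ingredients aimed at dense small targets:

* **DySample** — content-aware upsampling: each output pixel reads the input
  at a regular-grid position plus a learned offset (bounded by a 0.25-cell
  scope), via bilinear interpolation.  With zero offsets it *is* bilinear
  upsampling.
* **SSFF** — scale-sequence feature fusion: deeper pyramid levels are
  channel-aligned, dynamically upsampled to a reference level, smoothed with
  a normalized Gaussian (the scale-space view of the pyramid), stacked along
  a new scale axis and reduced by a 3-D convolution with kernel
  (depth, 1, 1).
* **TFE** — triple feature encoding: consecutive large/medium/small levels
  are width-aligned, the large one downsampled by the element-wise mean of
  max- and average-pooling, the small one upsampled by nearest neighbour,
  and the three concatenated along channels.
* **P2** — an extra stride-4 fusion level (160 x 160 at 640 input) feeding a
  fourth detection head, so targets a few pixels wide survive the pyramid.

A plain PAN neck (three outputs) is provided as the baseline counterpart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .blocks import C2f, CBS
from .nn import functional as F

__all__ = [
    "GaussianSpec", "gaussian_kernel", "gaussian_smooth", "DySample",
    "TFE", "SSFF", "PANNeck", "DyASFP2Neck", "NeckConfig", "build_neck",
]


# ----------------------------------------------------------------- Gaussian
@dataclass(frozen=True)
class GaussianSpec:
    """Isotropic Gaussian smoothing kernel: G(w, h) ~ exp(-(w^2+h^2)/2s^2)."""

    sigma: float = 1.0
    radius: int | None = None  # half-width; defaults to ceil(2*sigma)

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def r(self) -> int:
        return self.radius if self.radius is not None else max(1, math.ceil(2 * self.sigma))


def gaussian_kernel(spec: GaussianSpec, normalize: bool = True) -> np.ndarray:
    """Discrete sampling of the 2-D Gaussian on an odd grid; renormalized to
    sum 1 unless ``normalize`` is off (then the center equals 1/(2 pi s^2))."""
    r = spec.r
    ax = np.arange(-r, r + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * spec.sigma**2)) / (2.0 * np.pi * spec.sigma**2)
    if normalize:
        k = k / k.sum()
    return k


def gaussian_smooth(x, spec: GaussianSpec):
    """Per-channel convolution with the normalized kernel; reflect padding
    keeps the spatial size and preserves constants exactly."""
    x = nn.as_tensor(x)
    C = x.shape[1]
    k = gaussian_kernel(spec)
    w = nn.Tensor(np.broadcast_to(k[None, None], (C, 1, *k.shape)).astype(x.dtype).copy())
    xp = F.pad2d(x, spec.r, mode="reflect")
    return F.conv2d(xp, w, stride=1, padding=0, groups=C)


# ------------------------------------------------------------------ DySample
class DySample(nn.Module):
    """Dynamic upsampling by an integer factor.

    A 1x1 convolution predicts, for each of ``groups`` channel groups, a 2-D
    offset per output pixel (in input-pixel units, scaled by ``scope``); the
    output is the input bilinearly sampled at half-pixel grid + offset.
    """

    def __init__(self, c_in, factor: int = 2, groups: int = 4, scope: float = 0.25):
        super().__init__()
        if factor < 2:
            raise ValueError(f"upsampling factor must be >= 2, got {factor}")
        while c_in % groups:
            groups -= 1
        self.factor, self.groups, self.scope = factor, groups, scope
        self.offset = nn.Conv2d(c_in, 2 * groups * factor * factor, 1, bias=True)
        # start near plain bilinear upsampling
        self.offset.weight.data *= 1e-3
        self.offset.bias.data[...] = 0.0

    def forward(self, x):
        x = nn.as_tensor(x)
        N, C, H, W = x.shape
        r, G = self.factor, self.groups
        off = self.offset(x) * self.scope
        off = F.pixel_shuffle(off, r)                    # (N, 2G, rH, rW)
        off = off.reshape(N, 2, G, r * H, r * W)
        base_x = (np.arange(r * W, dtype=np.float32) + 0.5) / r - 0.5
        base_y = (np.arange(r * H, dtype=np.float32) + 0.5) / r - 0.5
        px = off[:, 0] + base_x[None, None, None, :]
        py = off[:, 1] + base_y[None, None, :, None]
        return F.grid_sample(x, px, py)


# ----------------------------------------------------------------------- TFE
class TFE(nn.Module):
    """Triple feature encoding of three consecutive pyramid levels.

    Branch widths are aligned to ``width`` by 1x1 CBS convolutions; the
    fusion stage itself (pooling mean for the large branch, nearest for the
    small one, channel concat) is exposed as :meth:`fuse`.
    """

    def __init__(self, c_large, c_medium, c_small, width):
        super().__init__()
        self.adj_l = CBS(c_large, width, 1)
        self.adj_m = CBS(c_medium, width, 1)
        self.adj_s = CBS(c_small, width, 1)
        self.width = width

    @staticmethod
    def fuse(large, medium, small):
        l_down = (F.max_pool2d(large, 2, 2) + F.avg_pool2d(large, 2, 2)) * 0.5
        s_up = F.upsample_nearest(small, 2)
        return nn.concat([l_down, medium, s_up], axis=1)

    def forward(self, large, medium, small):
        lh, mh = large.shape[-1], medium.shape[-1]
        if lh != 2 * mh or mh != 2 * small.shape[-1]:
            raise ValueError("TFE expects consecutive pyramid scales (2x steps)")
        return self.fuse(self.adj_l(large), self.adj_m(medium), self.adj_s(small))


# ---------------------------------------------------------------------- SSFF
class SSFF(nn.Module):
    """Scale-sequence fusion of ``depth`` levels onto the shallowest one.

    ``in_channels`` are ordered deepest to shallowest; the last entry is the
    reference level whose spatial size the output keeps.  The scale-axis
    reduction is a 3-D convolution with kernel (depth, 1, 1), stored
    flattened as an equivalent 1x1 2-D convolution over the stacked levels.
    """

    def __init__(self, in_channels, width, sigma: float = 1.0,
                 dysample_groups: int = 4, dysample_scope: float = 0.25):
        super().__init__()
        d = len(in_channels)
        self.align = nn.ModuleList([CBS(c, width, 1) for c in in_channels])
        self.up = nn.ModuleList([
            DySample(width, 2 ** (d - 1 - i), dysample_groups, dysample_scope)
            for i in range(d - 1)
        ])
        self.spec = GaussianSpec(sigma)
        self.reduce = nn.Conv2d(d * width, width, 1, bias=False)
        self.bn = nn.BatchNorm2d(width)
        self.width = width

    def forward(self, levels):
        if len(levels) != len(self.align._list):
            raise ValueError("level count mismatch")
        ref_w = levels[-1].shape[-1]
        seq = []
        for i, lv in enumerate(levels):
            y = self.align[i](lv)
            if i < len(self.up._list):
                if lv.shape[-1] * self.up[i].factor != ref_w:
                    raise ValueError("levels must be consecutive power-of-two scales")
                y = gaussian_smooth(self.up[i](y), self.spec)
            seq.append(y)
        return self.bn(self.reduce(nn.concat(seq, axis=1))).silu()


# ---------------------------------------------------------------------- necks
class PANNeck(nn.Module):
    """Stock top-down/bottom-up path-aggregation neck (three outputs)."""

    def __init__(self, c3, c4, c5, n=1):
        super().__init__()
        self.c2f_td4 = C2f(c4 + c5, c4, n)
        self.c2f_td3 = C2f(c3 + c4, c3, n)
        self.down3 = CBS(c3, c3, 3, 2)
        self.c2f_bu4 = C2f(c3 + c4, c4, n)
        self.down4 = CBS(c4, c4, 3, 2)
        self.c2f_bu5 = C2f(c4 + c5, c5, n)

    def forward(self, feats):
        p3, p4, p5 = feats[-3:]
        t4 = self.c2f_td4(nn.concat([F.upsample_nearest(p5, 2), p4], axis=1))
        t3 = self.c2f_td3(nn.concat([F.upsample_nearest(t4, 2), p3], axis=1))
        b4 = self.c2f_bu4(nn.concat([self.down3(t3), t4], axis=1))
        b5 = self.c2f_bu5(nn.concat([self.down4(b4), p5], axis=1))
        return [t3, b4, b5]


@dataclass
class NeckConfig:
    """Channel plan of the DyASF-P2 neck.

    ``in_channels``: backbone P2..P5 widths; ``out_channels``: the four head
    input widths; ``tfe_width_hi``/``tfe_width_lo``: branch widths of the
    deep (P3/P4/P5) and shallow (P2/P3/P4) TFE; ``mid3``: stride-8 trunk
    width; ``sigma``: Gaussian scale per SSFF; ``dysample_*``: sampler
    options.
    """

    in_channels: tuple = (32, 64, 128, 256)
    out_channels: tuple = (80, 64, 96, 128)
    tfe_width_hi: int = 128
    tfe_width_lo: int = 80
    mid3: int = 84
    sigma: float = 1.0
    dysample_groups: int = 4
    dysample_scope: float = 0.25
    depth: int = 1


class DyASFP2Neck(nn.Module):
    """Four-level fusion neck: two TFEs, two dynamic SSFFs, and a P2 layer.

    Wiring (stride / resolution at 640 input):

    * stride 16: TFE(P3, P4, P5) -> C2f -> N4 (40 x 40)
    * stride 8:  TFE(P2, P3, P4) -> C2f, plus SSFF(P5, P4, P3) added in -> N3
    * stride 4:  DySample(N3) ++ P2 -> C2f, plus SSFF(N4, N3, .) added -> N2
    * strides 8/16/32 heads: PAN-style downward path over N3/N4/P5
    """

    def __init__(self, cfg: NeckConfig = NeckConfig()):
        super().__init__()
        c2, c3, c4, c5 = cfg.in_channels
        o2, o3, o4, o5 = cfg.out_channels
        n = cfg.depth
        self.cfg = cfg
        self.tfe_hi = TFE(c3, c4, c5, cfg.tfe_width_hi)
        self.c2f_n4 = C2f(3 * cfg.tfe_width_hi, o4, n)
        self.tfe_lo = TFE(c2, c3, c4, cfg.tfe_width_lo)
        self.c2f_n3 = C2f(3 * cfg.tfe_width_lo, cfg.mid3, n)
        self.ssff3 = SSFF((c5, c4, c3), cfg.mid3, cfg.sigma,
                          cfg.dysample_groups, cfg.dysample_scope)
        self.up2 = DySample(cfg.mid3, 2, cfg.dysample_groups, cfg.dysample_scope)
        self.c2f_n2 = C2f(cfg.mid3 + c2, o2, n)
        self.ssff2 = SSFF((o4, cfg.mid3, o2), o2, cfg.sigma,
                          cfg.dysample_groups, cfg.dysample_scope)
        self.down2 = CBS(o2, o2, 3, 2)
        self.c2f_o3 = C2f(o2 + cfg.mid3, o3, n)
        self.down3 = CBS(o3, o3, 3, 2)
        self.c2f_o4 = C2f(o3 + o4, o4, n)
        self.down4 = CBS(o4, o4, 3, 2)
        self.c2f_o5 = C2f(o4 + c5, o5, n)

    def forward(self, feats):
        p2, p3, p4, p5 = feats[-4:]
        n4 = self.c2f_n4(self.tfe_hi(p3, p4, p5))
        n3 = self.c2f_n3(self.tfe_lo(p2, p3, p4)) + self.ssff3([p5, p4, p3])
        n2 = self.c2f_n2(nn.concat([self.up2(n3), p2], axis=1))
        n2 = n2 + self.ssff2([n4, n3, n2])
        o3 = self.c2f_o3(nn.concat([self.down2(n2), n3], axis=1))
        o4 = self.c2f_o4(nn.concat([self.down3(o3), n4], axis=1))
        o5 = self.c2f_o5(nn.concat([self.down4(o4), p5], axis=1))
        return [n2, o3, o4, o5]


def build_neck(cfg, p2: bool = True):
    """Factory: a DyASF-P2 neck from a :class:`NeckConfig`, or the baseline
    PAN neck (``p2=False``, using the last three ``in_channels``)."""
    if p2:
        return DyASFP2Neck(cfg)
    _, c3, c4, c5 = cfg.in_channels
    return PANNeck(c3, c4, c5, cfg.depth)
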