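"""Lightweight shared detail-enhanced detection head (LSDECD).

Head layout per pyramid level: a level-specific 1x1 convolution with group
normalization projects the level to a shared working width; then the *same*
two 3x3 detail-enhanced convolution (DEConv) blocks — one parameter set,
applied at every level — aggregate spatial detail; finally shared decoupled
1x1 classification and box-regression convolutions produce the output maps,
with a per-level learnable scalar on the regression feature path to absorb
the scale statistics of each stride.

DEConv sums five parallel 3x3 convolutions: a vanilla one and four
difference convolutions whose effective kernels are tap-transformed so they
respond only to local structure, never to a constant signal:

* central difference:   e = w - (sum of all taps) placed on the center tap;
* angular difference:   e = w - w rotated one step around the center
  (outer taps cycled clockwise, center fixed);
* horizontal difference: e = w minus its per-row mean (each row of e sums
  to 0, so horizontally flat signals are annihilated);
* vertical difference:   e = w minus its per-column mean.

All transformations are linear in the weights, so the five branches fuse
exactly into one 3x3 kernel for deployment (:func:`deconv_fuse`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F

__all__ = ["HeadConfig", "DEConv", "deconv_fuse", "LSDECDHead"]


@dataclass(frozen=True)
class HeadConfig:
    num_levels: int = 4
    num_classes: int = 5
    reg_max: int = 16
    width: int = 24           # shared working width
    gn_groups: int = 16

    def __post_init__(self):
        if self.num_levels not in (3, 4):
            raise ValueError("num_levels must be 3 or 4")
        if self.num_classes < 1 or self.reg_max < 1:
            raise ValueError("nc and reg_max must be >= 1")


# --------------------------------------------------------------------- DEConv
def _effective_kernels(banks: dict) -> dict:
    """Tap-transform each difference bank into its effective 3x3 kernel."""
    out = {"vanilla": banks["vanilla"]}
    cd = banks["cd"]
    e = cd.copy()
    e[..., 1, 1] -= cd.sum(axis=(-2, -1))
    out["cd"] = e
    ad = banks["ad"]
    # outer taps in clockwise order around the center
    ring = [(0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0)]
    rot = ad.copy()
    for (ra, ca), (rb, cb) in zip(ring, ring[1:] + ring[:1]):
        rot[..., rb, cb] = ad[..., ra, ca]
    out["ad"] = ad - rot
    hd = banks["hd"]
    out["hd"] = hd - hd.mean(axis=-1, keepdims=True)
    vd = banks["vd"]
    out["vd"] = vd - vd.mean(axis=-2, keepdims=True)
    return out


class DEConv(nn.Module):
    """Detail-enhanced 3x3 convolution (five fusable parallel banks)."""

    BANKS = ("vanilla", "cd", "ad", "hd", "vd")

    def __init__(self, c_in, c_out, bias=True):
        super().__init__()
        rng = nn.init_rng()
        bound = 1.0 / np.sqrt(c_in * 9)
        for name in self.BANKS:
            setattr(self, f"w_{name}",
                    nn.Parameter(rng.uniform(-bound, bound, (c_out, c_in, 3, 3))))
        self.bias = nn.Parameter(rng.uniform(-bound, bound, c_out)) if bias else None

    def banks(self) -> dict:
        return {n: getattr(self, f"w_{n}").data for n in self.BANKS}

    def fused_kernel(self) -> np.ndarray:
        """Single 3x3 kernel equivalent to the five-branch sum."""
        eff = _effective_kernels(self.banks())
        return sum(eff.values())

    def forward(self, x):
        """Sum of the five branch convolutions.

        Each branch convolves with its tap-transformed kernel; the transform
        is applied to the weight tensor with autodiff ops so training sees
        the correct gradients.  (For inference the fused kernel gives the
        identical result; see :func:`deconv_fuse`.)
        """
        return self._apply_kernel(x, self._effective_tensor())

    def _effective_tensor(self) -> nn.Tensor:
        w_v = self.w_vanilla
        cd = self.w_cd
        center_mask = np.zeros((1, 1, 3, 3), dtype=cd.dtype)
        center_mask[..., 1, 1] = 1.0
        cd_eff = cd - cd.sum(axis=(-2, -1), keepdims=True) * nn.Tensor(center_mask)
        ad = self.w_ad
        ring = [(0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0)]
        src = np.arange(9).reshape(3, 3)
        dst = np.arange(9).reshape(3, 3).copy()
        for (ra, ca), (rb, cb) in zip(ring, ring[1:] + ring[:1]):
            dst[rb, cb] = src[ra, ca]
        flat = ad.reshape(*ad.shape[:2], 9)
        rot = flat[:, :, dst.reshape(-1)].reshape(*ad.shape)
        ad_eff = ad - rot
        hd = self.w_hd
        hd_eff = hd - hd.mean(axis=-1, keepdims=True)
        vd = self.w_vd
        vd_eff = vd - vd.mean(axis=-2, keepdims=True)
        return w_v + cd_eff + ad_eff + hd_eff + vd_eff

    def forward_branches(self, x):
        """Explicit five-branch sum (reference path for equivalence checks)."""
        eff = _effective_kernels(self.banks())
        out = None
        for k in eff.values():
            y = F.conv2d(nn.as_tensor(x), nn.Tensor(k.astype(np.float32)),
                         stride=1, padding=1)
            out = y if out is None else out + y
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1, 1, 1)
        return out

    def _apply_kernel(self, x, w):
        return F.conv2d(nn.as_tensor(x), w, self.bias, stride=1, padding=1)


def deconv_fuse(block: DEConv) -> np.ndarray:
    """Deployment-time re-parameterization: one kernel, same output."""
    return block.fused_kernel()


# ----------------------------------------------------------------------- head
class _ConvGN(nn.Module):
    def __init__(self, c_in, c_out, k, gn_groups):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, k, bias=False)
        self.gn = nn.GroupNorm(gn_groups, c_out)

    def forward(self, x):
        return self.gn(self.conv(x)).silu()


class _DEConvGN(nn.Module):
    def __init__(self, c, gn_groups):
        super().__init__()
        self.conv = DEConv(c, c, bias=False)
        self.gn = nn.GroupNorm(gn_groups, c)

    def forward(self, x):
        return self.gn(self.conv(x)).silu()


class LSDECDHead(nn.Module):
    """Shared detail-enhanced head over 3 or 4 pyramid levels.

    Returns per level ``(cls_map, box_map)`` with ``nc`` and ``4*reg_max``
    channels.  Only the entry 1x1 projections and the regression scale are
    level-specific; both DEConv blocks and both prediction convolutions are
    one shared parameter set.
    """

    def __init__(self, in_channels, cfg: HeadConfig = HeadConfig()):
        super().__init__()
        if len(in_channels) != cfg.num_levels:
            raise ValueError(f"expected {cfg.num_levels} input levels, "
                             f"got {len(in_channels)}")
        self.cfg = cfg
        w = cfg.width
        self.entry = nn.ModuleList([_ConvGN(c, w, 1, cfg.gn_groups)
                                    for c in in_channels])
        self.shared1 = _DEConvGN(w, cfg.gn_groups)
        self.shared2 = _DEConvGN(w, cfg.gn_groups)
        self.cls_pred = nn.Conv2d(w, cfg.num_classes, 1, bias=True)
        self.cls_pred.bias.data[...] = -4.6  # ~1% object prior
        self.reg_pred = nn.Conv2d(w, 4 * cfg.reg_max, 1, bias=True)
        self.reg_pred.bias.data[...] = 1.0
        self.scales = nn.ModuleList([_Scale() for _ in in_channels])

    def forward(self, levels):
        if len(levels) != len(self.entry._list):
            raise ValueError("level count mismatch")
        out = []
        for i, x in enumerate(levels):
            y = self.shared2(self.shared1(self.entry[i](x)))
            cls = self.cls_pred(y)
            box = self.reg_pred(self.scales[i](y))
            out.append((cls, box))
        return out


class _Scale(nn.Module):
    """Per-level learnable scalar, initialized to 1 (identity)."""

    def __init__(self):
        super().__init__()
        self.s = nn.Parameter(np.ones(1))

    def forward(self, x):
        return x * self.s.reshape(1, 1, 1, 1)
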