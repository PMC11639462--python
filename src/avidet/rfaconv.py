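"""Receptive-Field Attention convolution (RFAConv).

A drop-in replacement for a k x k convolution that stops treating the k^2
taps of every receptive field as interchangeable: each channel expands into
k^2 receptive-field feature slots (a grouped k x k convolution), an
attention branch (average pooling -> 1x1 group convolution -> softmax over
the k^2 slots) scores how important each slot is at each spatial site, and
the weighted slots are re-tiled into a k-times-larger map that a final
k-stride-k convolution reduces to the output channels.  The output spatial
size therefore equals that of the standard convolution it replaces.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .nn import functional as F

__all__ = ["RFABlockConfig", "RFAConv", "rfa_weights", "rfaconv_forward"]


@dataclass(frozen=True)
class RFABlockConfig:
    in_channels: int
    out_channels: int
    k: int = 3
    stride: int = 1

    def __post_init__(self):
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError(f"kernel must be odd and >= 3, got {self.k}")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")


class RFAConv(nn.Module):
    """Receptive-field attention convolution block.

    The attention branch and the feature branch are grouped per input
    channel (every channel owns its k^2 slots); the final fusion is a
    standard convolution with kernel k and stride k over the re-tiled map,
    followed by batch normalization and SiLU so the block can replace a
    CBS convolution one-for-one.
    """

    def __init__(self, c_in, c_out, k=3, stride=1):
        super().__init__()
        cfg = RFABlockConfig(c_in, c_out, k, stride)
        self.cfg = cfg
        kk = k * k
        self.weight_conv = nn.Conv2d(c_in, c_in * kk, 1, groups=c_in, bias=False)
        self.feat_conv = nn.Conv2d(c_in, c_in * kk, k, stride=stride,
                                   padding=k // 2, groups=c_in, bias=False)
        self.feat_bn = nn.BatchNorm2d(c_in * kk)
        self.out_conv = nn.Conv2d(c_in, c_out, k, stride=k, padding=0, bias=False)
        self.out_bn = nn.BatchNorm2d(c_out)

    def attention(self, x) -> nn.Tensor:
        """A_rf: softmax-normalized slot weights, shape (N, C*k^2, H', W')."""
        k = self.cfg.k
        pooled = F.avg_pool2d(x, k, stride=self.cfg.stride, padding=k // 2)
        logits = self.weight_conv(pooled)
        N, _, H, W = logits.shape
        w = logits.reshape(N, self.cfg.in_channels, k * k, H, W).softmax(axis=2)
        return w.reshape(N, self.cfg.in_channels * k * k, H, W)

    def forward(self, x):
        k = self.cfg.k
        a = self.attention(x)
        f = self.feat_bn(self.feat_conv(x)).relu()
        weighted = a * f
        N, _, H, W = weighted.shape
        c = self.cfg.in_channels
        # (N, C*k^2, H, W) -> (N, C, kH, kW): slot (i, j) of each channel
        # becomes pixel (i, j) of its k x k tile
        tiled = (weighted.reshape(N, c, k, k, H, W)
                         .transpose(0, 1, 4, 2, 5, 3)
                         .reshape(N, c, k * H, k * W))
        return self.out_bn(self.out_conv(tiled)).silu()


def rfa_weights(x, cfg: RFABlockConfig, block: RFAConv | None = None) -> nn.Tensor:
    """Functional view of the attention map for a given configuration."""
    block = block or RFAConv(cfg.in_channels, cfg.out_channels, cfg.k, cfg.stride)
    return block.attention(nn.as_tensor(x))


def rfaconv_forward(x, cfg: RFABlockConfig, block: RFAConv | None = None) -> nn.Tensor:
    block = block or RFAConv(cfg.in_channels, cfg.out_channels, cfg.k, cfg.stride)
    return block(nn.as_tensor(x))
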