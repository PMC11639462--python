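"""Standard detector building blocks: CBS convolution, C2f, SPPF.

These are the stock backbone/neck ingredients of the anchor-free one-stage
detector family the toolkit extends; the novel blocks live in
:mod:`avidet.rfaconv`, :mod:`avidet.dyasf` and :mod:`avidet.lsdecd`.
"""

from __future__ import annotations

from . import nn
from .nn import functional as F


class CBS(nn.Module):
    """Conv + BatchNorm + SiLU."""

    def __init__(self, c_in, c_out, k=1, stride=1, padding=None, groups=1):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, k, stride, padding, groups, bias=False)
        self.bn = nn.BatchNorm2d(c_out)

    def forward(self, x):
        return self.bn(self.conv(x)).silu()


class Bottleneck(nn.Module):
    def __init__(self, c_in, c_out, shortcut=True, k=(3, 3), e=1.0):
        super().__init__()
        ch = int(c_out * e)
        self.cv1 = CBS(c_in, ch, k[0])
        self.cv2 = CBS(ch, c_out, k[1])
        self.add = shortcut and c_in == c_out

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C2f(nn.Module):
    """Cross-stage partial block with two-way fusion."""

    def __init__(self, c_in, c_out, n=1, shortcut=False):
        super().__init__()
        self.c = c_out // 2
        self.cv1 = CBS(c_in, 2 * self.c, 1)
        self.cv2 = CBS((2 + n) * self.c, c_out, 1)
        self.m = nn.ModuleList([Bottleneck(self.c, self.c, shortcut) for _ in range(n)])

    def forward(self, x):
        y = self.cv1(x)
        parts = [y[:, :self.c], y[:, self.c:]]
        for b in self.m:
            parts.append(b(parts[-1]))
        return self.cv2(nn.concat(parts, axis=1))


class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): three chained 5x5 max-pools."""

    def __init__(self, c_in, c_out, k=5):
        super().__init__()
        ch = c_in // 2
        self.cv1 = CBS(c_in, ch, 1)
        self.cv2 = CBS(ch * 4, c_out, 1)
        self.k = k

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(F.max_pool2d(y[-1], self.k, 1, self.k // 2))
        return self.cv2(nn.concat(y, axis=1))
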