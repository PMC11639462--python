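"""Neural-network layer/module abstractions over the autodiff tensors."""

from __future__ import annotations

import math

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "set_seed", "init_rng", "Parameter", "Module", "Sequential", "ModuleList",
    "Conv2d", "Linear", "BatchNorm2d", "GroupNorm", "SiLU", "ReLU", "Identity",
    "Upsample", "MaxPool2d", "SGD",
]

_RNG = np.random.default_rng(0)


def set_seed(seed: int):
    """Seed parameter initialization (call before building a model)."""
    global _RNG
    _RNG = np.random.default_rng(seed)


def init_rng() -> np.random.Generator:
    return _RNG


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal module tree: parameter registration, modes, state dicts."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- traversal -----------------------------------------------------------
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def num_params(self) -> int:
        """Exact count of trainable scalars."""
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        self.training = mode
        for _, c in self._children():
            c.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization -------------------------------------------------------
    def state_dict(self) -> dict:
        d = {k: p.data.copy() for k, p in self.named_parameters()}
        d.update({"buf:" + k: v.copy() for k, v in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict):
        for k, p in self.named_parameters():
            p.data = np.asarray(d[k], dtype=p.data.dtype).reshape(p.shape)
        for k, v in self.named_buffers():
            v[...] = d["buf:" + k]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = ModuleList(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = list(mods)
        for i, m in enumerate(self._list):
            setattr(self, f"m{i}", m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def append(self, m):
        setattr(self, f"m{len(self._list)}", m)
        self._list.append(m)


class Conv2d(Module):
    def __init__(self, c_in, c_out, k=1, stride=1, padding=None, groups=1, bias=True):
        super().__init__()
        if padding is None:
            padding = k // 2
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = c_in // groups * k * k
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Parameter(_RNG.uniform(-bound, bound, (c_out, c_in // groups, k, k)))
        self.bias = Parameter(_RNG.uniform(-bound, bound, c_out)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class Linear(Module):
    def __init__(self, c_in, c_out, bias=True):
        super().__init__()
        bound = 1.0 / math.sqrt(c_in)
        self.weight = Parameter(_RNG.uniform(-bound, bound, (c_out, c_in)))
        self.bias = Parameter(_RNG.uniform(-bound, bound, c_out)) if bias else None

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.03):
        super().__init__()
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.eps, self.momentum = eps, momentum

    def forward(self, x):
        sh = (1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(sh))
            var = Tensor(self.running_var.reshape(sh))
        xn = (x - mu) / (var + self.eps) ** 0.5
        return xn * self.weight.reshape(sh) + self.bias.reshape(sh)


class GroupNorm(Module):
    def __init__(self, num_groups, c, eps=1e-5):
        super().__init__()
        self.g = min(num_groups, c)
        while c % self.g:
            self.g -= 1
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))
        self.eps = eps

    def forward(self, x):
        N, C, H, W = x.shape
        xg = x.reshape(N, self.g, C // self.g * H * W)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=2, keepdims=True)
        xn = ((xg - mu) / (var + self.eps) ** 0.5).reshape(N, C, H, W)
        sh = (1, -1, 1, 1)
        return xn * self.weight.reshape(sh) + self.bias.reshape(sh)


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Identity(Module):
    def forward(self, x):
        return x


class Upsample(Module):
    def __init__(self, factor=2, mode="nearest"):
        super().__init__()
        self.factor, self.mode = factor, mode

    def forward(self, x):
        if self.mode == "nearest":
            return F.upsample_nearest(x, self.factor)
        return F.interpolate_bilinear(x, self.factor)


class MaxPool2d(Module):
    def __init__(self, k, stride=None, padding=0):
        super().__init__()
        self.k, self.stride, self.padding = k, stride or k, padding

    def forward(self, x):
        return F.max_pool2d(x, self.k, self.stride, self.padding)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr=0.01, momentum=0.9, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.momentum, self.wd = lr, momentum, weight_decay
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.wd:
                g = g + self.wd * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
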