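"""Gaussian scale-space tools, DySample, TFE/SSFF fusion and the necks."""

import numpy as np
import pytest
from scipy.signal import convolve2d

from avidet import nn
from avidet.dyasf import (DySample, DyASFP2Neck, GaussianSpec, NeckConfig,
                          PANNeck, SSFF, TFE, build_neck, gaussian_kernel,
                          gaussian_smooth)
from avidet.nn import functional as F


@pytest.fixture(autouse=True)
def _seed():
    nn.set_seed(11)


# ------------------------------------------------------------------ Gaussian
def test_gaussian_kernel_center_and_normalization():
    k = gaussian_kernel(GaussianSpec(1.0), normalize=False)
    c = k.shape[0] // 2
    assert k[c, c] == pytest.approx(1 / (2 * np.pi), abs=1e-12)
    for sigma in (0.5, 1.0, 2.3):
        kn = gaussian_kernel(GaussianSpec(sigma))
        assert kn.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(kn, kn[::-1, ::-1])  # G(w,h) = G(-w,-h)


def test_gaussian_requires_positive_sigma():
    with pytest.raises(ValueError):
        GaussianSpec(0.0)


def test_smoothing_preserves_constants_and_impulse(rng):
    c = nn.Tensor(np.full((1, 3, 10, 10), 2.5, dtype=np.float32))
    assert np.allclose(gaussian_smooth(c, GaussianSpec(1.0)).data, 2.5, atol=1e-6)
    spec = GaussianSpec(1.0)
    x = np.zeros((1, 1, 11, 11), dtype=np.float32)
    x[0, 0, 5, 5] = 1.0
    out = gaussian_smooth(nn.Tensor(x), spec).data[0, 0]
    k = gaussian_kernel(spec)
    r = spec.r
    assert np.allclose(out[5 - r:5 + r + 1, 5 - r:5 + r + 1], k, atol=1e-6)


def test_smoothing_matches_direct_convolution_and_reduces_tv(rng):
    spec = GaussianSpec(1.3)
    x = rng.normal(size=(1, 2, 12, 12)).astype(np.float32)
    out = gaussian_smooth(nn.Tensor(x), spec).data
    k = gaussian_kernel(spec)
    for ch in range(2):
        ref = convolve2d(np.pad(x[0, ch], spec.r, mode="reflect"),
                         k[::-1, ::-1], mode="valid")
        assert np.allclose(out[0, ch], ref, atol=1e-5)

    def tv(a):
        return np.abs(np.diff(a, axis=-1)).sum() + np.abs(np.diff(a, axis=-2)).sum()

    assert tv(out) <= tv(x) + 1e-6


# ------------------------------------------------------------------ DySample
def test_dysample_zero_offsets_is_bilinear(rng):
    ds = DySample(8, 2)
    ds.offset.weight.data[...] = 0.0
    ds.offset.bias.data[...] = 0.0
    x = nn.Tensor(rng.normal(size=(1, 8, 16, 16)).astype(np.float32))
    ref = F.interpolate_bilinear(x, 2)
    assert np.abs(ds(x).data - ref.data).max() <= 1e-6


def test_dysample_constant_input(rng):
    ds = DySample(8, 2)
    x = nn.Tensor(np.full((1, 8, 6, 6), 1.75, dtype=np.float32))
    assert np.allclose(ds(x).data, 1.75, atol=1e-6)


def test_dysample_shape_and_factor_validation(rng):
    ds = DySample(8, 2)
    x = nn.Tensor(rng.normal(size=(1, 8, 16, 16)).astype(np.float32))
    assert ds(x).shape == (1, 8, 32, 32)
    with pytest.raises(ValueError):
        DySample(8, factor=1)


# ----------------------------------------------------------------- TFE / SSFF
def test_tfe_concatenates_constants(rng):
    a = nn.Tensor(np.full((1, 4, 16, 16), 1.0, dtype=np.float32))
    b = nn.Tensor(np.full((1, 4, 8, 8), 2.0, dtype=np.float32))
    c = nn.Tensor(np.full((1, 4, 4, 4), 3.0, dtype=np.float32))
    out = TFE.fuse(a, b, c)
    assert out.shape == (1, 12, 8, 8)
    assert np.allclose(out.data[:, :4], 1.0)
    assert np.allclose(out.data[:, 4:8], 2.0)
    assert np.allclose(out.data[:, 8:], 3.0)


def test_tfe_output_at_medium_size_with_3c_channels(rng):
    t = TFE(8, 16, 32, 16)
    out = t(nn.Tensor(rng.normal(size=(1, 8, 16, 16)).astype(np.float32)),
            nn.Tensor(rng.normal(size=(1, 16, 8, 8)).astype(np.float32)),
            nn.Tensor(rng.normal(size=(1, 32, 4, 4)).astype(np.float32)))
    assert out.shape == (1, 48, 8, 8)


def test_tfe_rejects_nonconsecutive_scales(rng):
    t = TFE(8, 16, 32, 16)
    with pytest.raises(ValueError):
        t(nn.Tensor(np.zeros((1, 8, 16, 16), dtype=np.float32)),
          nn.Tensor(np.zeros((1, 16, 16, 16), dtype=np.float32)),
          nn.Tensor(np.zeros((1, 32, 4, 4), dtype=np.float32)))


def test_ssff_reference_size_channels_and_determinism(rng):
    ss = SSFF((32, 16, 8), width=12)
    lv = [nn.Tensor(rng.normal(size=(1, 32, 4, 4)).astype(np.float32)),
          nn.Tensor(rng.normal(size=(1, 16, 8, 8)).astype(np.float32)),
          nn.Tensor(rng.normal(size=(1, 8, 16, 16)).astype(np.float32))]
    y1 = ss(lv)
    assert y1.shape == (1, 12, 16, 16)
    y2 = ss(lv)
    assert np.array_equal(y1.data, y2.data)


def test_ssff_rejects_wrong_level_count(rng):
    ss = SSFF((32, 16, 8), width=12)
    with pytest.raises(ValueError):
        ss([nn.Tensor(np.zeros((1, 32, 4, 4), dtype=np.float32))])


# --------------------------------------------------------------------- necks
def _pyramid(rng, chans, size):
    feats, s = [], size
    for c in chans:
        feats.append(nn.Tensor(rng.normal(size=(1, c, s, s)).astype(np.float32)))
        s //= 2
    return feats


def test_dyasf_p2_neck_emits_four_levels(rng):
    cfg = NeckConfig(in_channels=(8, 16, 32, 64), out_channels=(16, 16, 24, 32),
                     tfe_width_hi=24, tfe_width_lo=16, mid3=16)
    neck = build_neck(cfg, p2=True)
    feats = _pyramid(rng, (8, 16, 32, 64), 64)  # strides 4..32 of a 256 input
    outs = neck(feats)
    assert [o.shape[-1] for o in outs] == [64, 32, 16, 8]
    assert [o.shape[1] for o in outs] == [16, 16, 24, 32]
    assert all(np.isfinite(o.data).all() for o in outs)


def test_pan_neck_emits_three_levels(rng):
    cfg = NeckConfig(in_channels=(8, 16, 32, 64))
    neck = build_neck(cfg, p2=False)
    outs = neck(_pyramid(rng, (8, 16, 32, 64), 64))
    assert [o.shape[-1] for o in outs] == [32, 16, 8]
    assert [o.shape[1] for o in outs] == [16, 32, 64]


def test_neck_is_a_pure_function(rng):
    cfg = NeckConfig(in_channels=(8, 16, 32, 64), out_channels=(16, 16, 24, 32),
                     tfe_width_hi=24, tfe_width_lo=16, mid3=16)
    neck = DyASFP2Neck(cfg)
    feats = _pyramid(rng, (8, 16, 32, 64), 32)
    a = neck(feats)
    b = neck(feats)
    assert all(np.array_equal(x.data, y.data) for x, y in zip(a, b))
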