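import numpy as np
import pytest

from avidet.boxloss import BoundingBox


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_box_pair(rng, near=False):
    """A valid (pred, gt) pair; ``near`` biases toward overlapping boxes."""
    gx, gy = rng.uniform(-5, 5, 2)
    gw, gh = rng.uniform(0.5, 6, 2)
    if near:
        px = gx + rng.uniform(-0.4, 0.4) * gw
        py = gy + rng.uniform(-0.4, 0.4) * gh
        pw = gw * rng.uniform(0.6, 1.6)
        ph = gh * rng.uniform(0.6, 1.6)
    else:
        px, py = rng.uniform(-5, 5, 2)
        pw, ph = rng.uniform(0.5, 6, 2)
    return BoundingBox(px, py, pw, ph), BoundingBox(gx, gy, gw, gh)


@pytest.fixture(scope="session")
def easy_dataset(tmp_path_factory):
    """Small, easy synthetic detection dataset (large separated objects)."""
    from avidet.scenegen import DatasetSpec, SceneSpec, generate_dataset

    root = tmp_path_factory.mktemp("easy_ds")
    spec = SceneSpec(image_size=96, objects_range=(1, 3),
                     scale_range=(0.25, 0.5), occlusion_fraction=0.0,
                     clutter=0.25, seed=42)
    cfg = generate_dataset(root, DatasetSpec(total=150), spec)
    return cfg


@pytest.fixture(scope="session")
def small_model_cfg():
    """Reduced-width full bird variant for desk-scale training."""
    from avidet.assembly import ModelConfig

    return ModelConfig(variant="bird-small", width=0.125, depth=0.33,
                       rfaconv=True, dyasf_p2=True, lsdecd=True,
                       head_width=16, reg_max=8,
                       loss={"name": "inner_shape_iou"}, img_size=96, seed=5)
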