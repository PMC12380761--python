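import numpy as np
import pytest

from vegdet import nn, synth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(autouse=True)
def _seed_init():
    nn.seed(0)


def make_tiny_dataset(n: int, seed0: int, image_size: int = 96,
                      num_classes: int = 5):
    """Small-lesion scenes at reduced resolution for fast training tests."""
    cfg = synth.GeneratorConfig(image_size=image_size,
                                lesion_radius_range=(2.5, 10.0),
                                small_fraction=0.7, small_radius_max=6.0)
    out = []
    for i in range(n):
        spec = synth.sample_scene(i % num_classes, seed=seed0 + i, cfg=cfg)
        out.append(synth.generate_scene(spec))
    return out


@pytest.fixture(scope="session")
def tiny_train_data():
    return make_tiny_dataset(24, 1000)


@pytest.fixture(scope="session")
def tiny_val_data():
    return make_tiny_dataset(10, 9000)
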