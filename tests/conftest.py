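import numpy as np
import pytest

from gcassn.io import LabeledCloud, normalize_cloud
from gcassn.model import ModelConfig
from gcassn.synthetic import PlantSpec, SoilSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest full pipeline: 1 GCASM layer, 16 channels, k=8."""
    return ModelConfig(n_classes=3, n_gcasm_layers=1, channels=(16,), k=8,
                       global_dim=64, head_dims=(32, 16))


@pytest.fixture(scope="session")
def small_plants():
    """Four normalized 128-point stem/leaf/soil plants."""
    template = PlantSpec(n_points=128)
    return [normalize_cloud(c)
            for c in generate_dataset(template, 4, seed=5, variation=0.1)]


@pytest.fixture(scope="session")
def two_class_plants():
    """Six normalized 128-point stem/leaf plants (no soil)."""
    template = PlantSpec(n_points=128, soil=SoilSpec(present=False))
    return [normalize_cloud(c)
            for c in generate_dataset(template, 6, seed=9, variation=0.1)]


@pytest.fixture
def random_cloud(rng):
    coords = rng.normal(size=(40, 3))
    labels = rng.integers(0, 3, size=40)
    return LabeledCloud(coords, labels, source_id="random")
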