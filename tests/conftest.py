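import numpy as np
import pytest

from plantseg3d import (ModelConfig, PlantSpec, PointCloud, SegmentationModel,
                        generate_plant)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model_config():
    """A deliberately small network for fast structural tests."""
    return ModelConfig(
        n_points=64, d_m=16, h=2, d_k=8, d_v=8, ffn_hidden=16,
        m_fps=16, k_local=24, radii=(0.2, 0.35, 0.6), radius_local=0.3,
        radius_point=0.25, k_max=8, rpc_hidden=8, c_r=8, c_a=4,
        highd_hidden=8, head_hidden=16, seed=7)


@pytest.fixture
def tiny_model(tiny_model_config):
    return SegmentationModel(tiny_model_config, seed=7)


@pytest.fixture
def small_plant():
    return generate_plant(PlantSpec(seed=11))


@pytest.fixture
def random_cloud(rng):
    return PointCloud(rng.uniform(-1, 1, size=(80, 3)))
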