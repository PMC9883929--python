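import numpy as np
import pytest

from podcount.annotations_io import ImageAnnotation
from podcount.boxes import Box
from podcount.network import ModelConfig, build_model
from podcount.synthetic import easy_scene_config, generate_scene


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    """Smallest practical model: quarter width, single bottlenecks, 64 px."""
    return ModelConfig(
        depth_multiplier=0.34,
        width_multiplier=0.25,
        mode="training",
        input_resolution=64,
        init_seed=0,
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return build_model(tiny_config)


@pytest.fixture(scope="session")
def easy_scenes():
    cfg = easy_scene_config(160, seed=3)
    return [generate_scene(cfg, i) for i in range(6)]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def simple_annotation():
    return ImageAnnotation(
        "img0",
        100,
        80,
        [Box(10, 10, 30, 40), Box(50, 20, 70, 60), Box(20, 50, 45, 70)],
    )
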