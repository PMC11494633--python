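import numpy as np
import pytest

from fdrmnet.backbone import StageConfig
from fdrmnet.data import SceneSpec, generate_scene
from fdrmnet.model import ModelConfig, build_model
from fdrmnet.neck import NeckConfig


def tiny_model_config(**overrides) -> ModelConfig:
    """A width-reduced config small enough for CPU test forwards."""
    kw = dict(
        backbone=StageConfig(
            stem_mid=8, stem_out=16, stage_mid=(8, 12, 16, 24), stage_out=(16, 24, 32, 48)
        ),
        neck=NeckConfig(branch=16, mid=32, out=32, affm_hidden=(16, 16, 16), ema_groups=4),
        head_width=32,
        head_depth=2,
        num_classes=1,
        input_size=96,
    )
    kw.update(overrides)
    return ModelConfig(**kw)


@pytest.fixture
def tiny_cfg() -> ModelConfig:
    return tiny_model_config()


@pytest.fixture
def tiny_model(tiny_cfg):
    return build_model(tiny_cfg, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def scene():
    return generate_scene(SceneSpec(image_size=(96, 96), seed=7))
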