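import numpy as np
import pytest

from fluolevel.detect import DetectConfig
from fluolevel.synthgen import SceneSpec, WellResponseModel


@pytest.fixture
def model() -> WellResponseModel:
    """Default 24-well water response model."""
    return WellResponseModel()


@pytest.fixture
def clean_scene() -> SceneSpec:
    """A noiseless centred circular spot, radius 50 px."""
    return SceneSpec(true_perimeter=2 * np.pi * 50.0)


@pytest.fixture
def detect_config() -> DetectConfig:
    return DetectConfig()
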