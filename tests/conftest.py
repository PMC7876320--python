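import numpy as np
import pytest

from facewave import CalibrationMatrices, SceneConfig


@pytest.fixture
def calib() -> CalibrationMatrices:
    return CalibrationMatrices()


@pytest.fixture
def small_scene() -> SceneConfig:
    """A quick-to-render scene used across module tests."""
    return SceneConfig(grid_shape=(24, 24), duration=60.0, phase_velocity=4.0, seed=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
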