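import numpy as np
import pytest

from olfactomap.atlas import default_source_atlas
from olfactomap.forward import SensorArray, default_sensor_array
from olfactomap.paradigm import build_schedule
from olfactomap.recording import SensorRecording


@pytest.fixture(scope="session")
def schedule4():
    """The four-run printed stimulus–rest schedule starting at t = 0."""
    return build_schedule(n_runs=4)


@pytest.fixture(scope="session")
def small_array():
    """16-channel magnetometer cap for cheap forward-model tests."""
    return default_sensor_array(16)


@pytest.fixture(scope="session")
def small_atlas():
    """Two dipoles per ROI — enough structure for unit tests."""
    return default_source_atlas(points_per_roi=2, spread=0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def make_recording(data: np.ndarray, rate: float = 100.0) -> SensorRecording:
    """Wrap a raw (channels × samples) array as a recording with a stub array."""
    n = data.shape[0]
    pos = np.tile([0.0, 0.0, 0.2], (n, 1)) + np.arange(n)[:, None] * [1e-3, 0, 0]
    ori = np.tile([0.0, 0.0, 1.0], (n, 1))
    arr = SensorArray(pos, ori, ["magnetometer"] * n)
    return SensorRecording(data, rate, arr)


@pytest.fixture
def flat_recording(schedule4):
    """Constant-zero 4-run recording at 100 Hz with 3 channels."""
    n_samples = int(schedule4.end * 100)
    return make_recording(np.zeros((3, n_samples)), rate=100.0)
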