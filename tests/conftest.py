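import numpy as np
import pytest

from itop.recording import GazeRecording
from itop.simulate import SimulationConfig, simulate_gaze


def make_recording(positions, valid=None, rate=100.0, rid="test"):
    positions = np.asarray(positions, dtype=float)
    if valid is None:
        valid = np.isfinite(positions).all(axis=1)
    return GazeRecording(rid, positions, np.asarray(valid, bool), rate)


@pytest.fixture
def six_sample_recording():
    """Two tight clusters of three samples each, 10 units apart."""
    pos = [(0, 0), (0, 0), (0, 1), (10, 0), (10, 0), (10, 1)]
    return make_recording(pos, rid="six")


@pytest.fixture
def noisy_recording():
    cfg = SimulationConfig(seed=7, n_fixations=3, noise_sd=0.3,
                           min_separation=3.0, fixation_duration=(15, 25),
                           id="fixture")
    rec, truth = simulate_gaze(cfg)
    return rec, truth


def random_mask(rng, n=20, p=0.45):
    return rng.random((n, n)) < p
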