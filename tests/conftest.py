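import numpy as np
import pytest

from emgknee import GaitSimConfig, TimeSeriesRecording, generate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """A 2-channel, 1 s recording with a linear angle ramp."""
    fs = 1000.0
    emg = rng.standard_normal((1000, 2))
    angle = np.linspace(0.0, 30.0, 100)
    return TimeSeriesRecording(
        emg=emg, emg_rate=fs, channel_labels=("LG", "MG"),
        angle=angle, angle_rate=100.0, subject_id="S1", trial_id="T1",
    )


@pytest.fixture(scope="session")
def tiny_subject():
    """Three short synthetic trials shared across tests (cheap to generate)."""
    cfg = GaitSimConfig(n_trials=3, trial_duration_s=6.0, seed=7)
    return cfg, generate_subject(cfg)
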