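import numpy as np
import pytest

from sttcnn.io import EEGRecording
from sttcnn.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """A 4-channel, 10 Hz, 6 s labeled recording with ratings."""
    return EEGRecording(
        data=rng.standard_normal((4, 60)).astype(np.float32),
        sampling_rate=10,
        channel_names=["C1", "C2", "C3", "C4"],
        subject_id="S01",
        trial_id="T01",
        discrete_label="positive",
        ratings={"valence": 7.5, "arousal": 2.5},
    )


@pytest.fixture(scope="session")
def reduced_dataset():
    """Small planted-signal dataset shared by training-level tests."""
    spec = SyntheticSpec.reduced(spatial_snr=3.0, temporal_snr=3.0, seed=11)
    return generate_dataset(spec, n_trials_per_class=2, task="pnn", window_seconds=1.0)
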