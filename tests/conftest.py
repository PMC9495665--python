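import numpy as np
import pytest

from ecgtune.combinations import CombinationSpec, prepare_task
from ecgtune.synth_ecg import BeatModel, ChannelSpec, generate_recording_set


@pytest.fixture(scope="session")
def beat():
    return BeatModel()


@pytest.fixture(scope="session")
def small_recording(beat):
    """Three-channel synthetic recording, small enough for fast training."""
    channels = [
        ChannelSpec("LEAD1", common_share=0.7),
        ChannelSpec("ECGA", common_share=0.7),
        ChannelSpec("ECGP", common_share=0.7),
    ]
    return generate_recording_set(beat, channels, fs=120.0, duration=10.0, seed=42)


@pytest.fixture(scope="session")
def small_task(small_recording):
    """Normalized 80-20 splits for predicting ECGP from LEAD1 + ECGA."""
    spec = CombinationSpec("P", "ECGP", ("LEAD1", "ECGA"))
    return prepare_task(small_recording, spec)


@pytest.fixture(scope="session")
def identity_data():
    """Noiseless y = x regression task, 1 input."""
    rng = np.random.default_rng(7)
    x = rng.uniform(0.0, 1.0, 1500)
    return (x[:1200], x[:1200].copy()), (x[1200:], x[1200:].copy())
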