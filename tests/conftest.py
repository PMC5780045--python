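import numpy as np
import pytest

import ephysflow as ef
from ephysflow.preprocess import epoch
from ephysflow.types import Channel


@pytest.fixture(scope="session")
def small_bank():
    """Reduced 12-frequency bank covering 10-25.9 Hz (includes beta)."""
    return ef.build_wavelet_bank(fmin=10.0, n=12)


@pytest.fixture(scope="session")
def small_events():
    return ef.generate_task_events(ef.TaskConfig(n_blocks=10, seed=7))


@pytest.fixture(scope="session")
def stn_channel():
    return [Channel("stn0", "stn-macro", "stn")]


@pytest.fixture(scope="session")
def null_epochs(small_events, stn_channel):
    """Epoched null recording at 500 Hz with a 500 ms buffer."""
    rec = ef.synthesize_lfp(small_events, ef.GroundTruth.null(), stn_channel,
                            fs=500.0, seed=11)
    return epoch(rec, small_events, buffer=500.0)


@pytest.fixture(scope="session")
def null_normpower(null_epochs, small_bank):
    wt = ef.wavelet_transform(null_epochs, small_bank)
    return ef.normalize_to_baseline(ef.power(wt))


def sinusoid_recording(freq, fs, duration_ms=30000.0, amp=1.0, phase=0.0,
                       name="stn0"):
    t = np.arange(int(duration_ms * fs / 1000.0)) / fs
    data = amp * np.cos(2 * np.pi * freq * t + phase)[np.newaxis, :]
    return ef.Recording(data=data, fs=fs,
                        channels=[Channel(name, "stn-macro", "stn")])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
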