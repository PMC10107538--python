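import numpy as np
import pytest

from neoseize.data_io import EEGRecording

LABELS8 = ["F3", "C3", "T3", "O1", "F4", "C4", "T4", "O2"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def labels8():
    return list(LABELS8)


def make_recording(data, fs=256.0, labels=None, **kw):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if labels is None:
        labels = LABELS8[: data.shape[0]]
    return EEGRecording(channel_labels=list(labels), fs=fs, data=data, **kw)


@pytest.fixture
def sine_epoch():
    """10 µV 2-Hz sinusoid on 8 channels, 120 s at 256 Hz."""
    fs = 256.0
    t = np.arange(0, 120, 1 / fs)
    x = 10.0 * np.sin(2 * np.pi * 2.0 * t)
    return make_recording(np.tile(x, (8, 1)), fs=fs)


@pytest.fixture
def noise_epoch(rng):
    """Band-limited (1–30 Hz) white noise, 8 channels, 120 s at 256 Hz."""
    from scipy import signal as sps

    fs = 256.0
    n = int(120 * fs)
    sos = sps.butter(8, [1.0, 30.0], btype="bandpass", fs=fs, output="sos")
    data = sps.sosfiltfilt(sos, rng.normal(size=(8, n))) * 20.0
    return make_recording(data, fs=fs)
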