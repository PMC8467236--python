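import numpy as np
import pytest

from apneabands import Epoch, Recording


def make_tone(freq_hz: float, fs: float = 200.0, seconds: float = 30.0,
              amplitude: float = 1.0) -> np.ndarray:
    t = np.arange(int(round(fs * seconds))) / fs
    return amplitude * np.sin(2 * np.pi * freq_hz * t)


@pytest.fixture
def tone_epoch():
    def _make(freq_hz, fs=200.0, seconds=30.0, amplitude=1.0):
        return Epoch("tone", 0, fs, make_tone(freq_hz, fs, seconds, amplitude))
    return _make


@pytest.fixture
def tone_recording():
    def _make(freq_hz, fs=200.0, seconds=60.0, amplitude=1.0, **kw):
        return Recording("tone", "C3-A2", fs, make_tone(freq_hz, fs, seconds, amplitude), **kw)
    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
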