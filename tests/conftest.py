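import numpy as np
import pytest

from emgcomb import Signal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_signal(rng):
    """A generic broadband test signal at 1 kHz."""
    return Signal(rng.standard_normal(5000), 1000.0)


def sinusoid(f, fs=1000.0, duration=2.0, amplitude=1.0, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return Signal(amplitude * np.sin(2 * np.pi * f * t + phase), fs)


@pytest.fixture
def make_sinusoid():
    return sinusoid
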