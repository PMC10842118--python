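import numpy as np
import pytest

from aadkit import MultichannelRecording, gen_poisson_cascades


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording():
    """Deterministic 3-channel recording: sinusoids plus fixed-seed noise."""
    rng = np.random.default_rng(7)
    fs = 200.0
    t = np.arange(int(6 * fs)) / fs
    data = np.vstack([
        np.sin(2 * np.pi * 10 * t) + 0.3 * rng.standard_normal(t.size),
        np.cos(2 * np.pi * 7 * t) + 0.3 * rng.standard_normal(t.size),
        0.5 * rng.standard_normal(t.size),
    ])
    return MultichannelRecording(data, fs, ["a", "b", "c"])


@pytest.fixture
def poisson_seq():
    return gen_poisson_cascades(rate=5.0, size_exponent=1.5, smin=1, smax=100,
                                n=3000, seed=3)
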