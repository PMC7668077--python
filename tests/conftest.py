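import numpy as np
import pytest

from ear2cortex.frontend import AudioSignal, FilterbankSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noise_audio(rng):
    """Half a second of peak-normalized white noise at 48 kHz."""
    x = rng.standard_normal(24000)
    return AudioSignal(x / np.max(np.abs(x)), 48000.0)


@pytest.fixture
def fspec16():
    return FilterbankSpec(n_channels=16)
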