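import numpy as np
import pytest

from fingerbci.io_streaming import CHANNELS, EEGTrial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_trial(rng):
    """Factory for small random trials."""

    def _make(n_samples=128, label="thumb", category="II", fs=128.0, scale=10.0):
        data = rng.normal(0.0, scale, (len(CHANNELS), n_samples))
        return EEGTrial(data=data, fs=fs, label=label, subject_category=category,
                        trial_id=f"{label}_test")

    return _make
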