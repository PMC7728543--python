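import numpy as np
import pytest

from tremorkit import TremorSimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_cfg():
    """Deterministic, noise-free pure-tone config on a perfect grid."""
    return TremorSimConfig(
        tremor_freq_hz=5.0,
        tremor_amp=1.0,
        freq_jitter_hz=0.0,
        noise_sd=0.0,
        jitter_model="none",
        seed=7,
    )
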