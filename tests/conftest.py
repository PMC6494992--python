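import numpy as np
import pytest

from ecggan import SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_windows():
    """Eight noisy synthetic windows of 50 samples at a reduced rate."""
    return generate_dataset(
        SynthConfig(duration=2.0, sampling_rate=50.0, seed=1),
        n_records=4,
        window_length=50,
    )


@pytest.fixture(scope="session")
def window_array(small_windows):
    return np.stack([w.values for w in small_windows])
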