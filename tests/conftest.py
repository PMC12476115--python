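import numpy as np
import pytest

from dynamap.synthetic import PhantomSpec, generate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, drift-free phantom: every contract is exact."""
    spec = PhantomSpec(
        shape=(12, 12, 12), n_timepoints=60, n_networks=3,
        drift_amplitude=0.0, noise_sigma=0.0, seed=7,
    )
    vol, truth = generate_subject(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-condition phantom with noise and drift."""
    spec = PhantomSpec(
        shape=(12, 12, 12), n_timepoints=60, n_networks=3, seed=11,
    )
    vol, truth = generate_subject(spec)
    return spec, vol, truth
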