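import numpy as np
import pytest

from erpstates import GeneratorConfig, make_fibonacci_montage, simulate_epochs


@pytest.fixture(scope="session")
def montage16():
    return make_fibonacci_montage(16)


@pytest.fixture(scope="session")
def montage128():
    return make_fibonacci_montage(128)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Small noiseless two-condition dataset: the analytic ground truth."""
    cfg = GeneratorConfig(
        n_subjects=3,
        n_trials_per_condition=6,
        n_channels=32,
        noise_sd=0.0,
        subject_topo_sd=0.0,
        seed=11,
    )
    return simulate_epochs(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Small dataset at the default noise level and planted 46-TF shift."""
    cfg = GeneratorConfig(
        n_subjects=6,
        n_trials_per_condition=10,
        n_channels=32,
        seed=12,
    )
    return simulate_epochs(cfg)
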