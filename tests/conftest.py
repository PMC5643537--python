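import numpy as np
import pytest

from microsyn import synthetic


@pytest.fixture(scope="session")
def small_config() -> synthetic.ExperimentConfig:
    """Reduced-rate configuration used across tests."""
    return synthetic.ExperimentConfig.demo()


@pytest.fixture(scope="session")
def truth4(small_config):
    cfg = synthetic.ExperimentConfig(n_states=4, eeg_rate=128.0)
    return synthetic.make_ground_truth(cfg, seed=11)


@pytest.fixture(scope="session")
def truth5():
    cfg = synthetic.ExperimentConfig(n_states=5, eeg_rate=128.0)
    return synthetic.make_ground_truth(cfg, seed=12)


@pytest.fixture(scope="session")
def resting_eeg(truth4):
    """60 s of clean-ish resting EEG at 128 Hz with its true labels."""
    rec, labels = synthetic.simulate_eeg(truth4, 60.0, 128.0, 8.0, seed=21)
    return rec, labels


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
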