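import numpy as np
import pytest

from mimodes import MiSimConfig, Signal, simulate_mi_trials, train_decoder


@pytest.fixture(scope="session")
def two_tone_signal() -> Signal:
    """sin(2*pi*1t) + 0.5*sin(2*pi*12t), 8 s at 250 Hz."""
    fs = 250.0
    t = np.arange(2000) / fs
    return Signal(np.sin(2 * np.pi * 1 * t) + 0.5 * np.sin(2 * np.pi * 12 * t), fs)


@pytest.fixture(scope="session")
def two_tone_parts():
    fs = 250.0
    t = np.arange(2000) / fs
    return {
        "slow": np.sin(2 * np.pi * 1 * t),
        "fast": 0.5 * np.sin(2 * np.pi * 12 * t),
    }


@pytest.fixture(scope="session")
def default_trainset():
    """The default synthetic fixture: 100 trials/class, ERD depth 0.5."""
    return simulate_mi_trials(MiSimConfig(n_trials_per_class=100, erd_depth=0.5, seed=42))


@pytest.fixture(scope="session")
def trained_decoder(default_trainset):
    """Decoder trained once and shared across pipeline/acceptance tests."""
    return train_decoder(default_trainset, fpr_max=0.10)


@pytest.fixture(scope="session")
def small_trainset():
    """Cheap fixture for I/O and CLI round trips."""
    return simulate_mi_trials(MiSimConfig(n_trials_per_class=5, seed=7))
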