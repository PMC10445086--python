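import numpy as np
import pytest

from clocktol import DatasetProfile, SignalSpec, generate_dataset


@pytest.fixture(scope="session")
def small_profile():
    return DatasetProfile("test", 60, 10.0, 50.0, "years")


@pytest.fixture(scope="session")
def small_signal():
    # small site panel so elastic-net fits stay fast in unit tests
    return SignalSpec(n_informative=40, n_noise=160, slope_magnitude=0.4, noise_sd=0.05)


@pytest.fixture(scope="session")
def small_dataset(small_profile, small_signal):
    return generate_dataset(small_profile, small_signal, seed=11)


@pytest.fixture(scope="session")
def noiseless_dataset():
    profile = DatasetProfile("clean", 200, 16.0, 88.0, "years")
    signal = SignalSpec(n_informative=50, n_noise=150, slope_magnitude=0.4, noise_sd=0.0)
    return generate_dataset(profile, signal, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
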