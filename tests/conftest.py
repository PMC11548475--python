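import numpy as np
import pytest

from emgconcord import SimulationConfig, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """A short session (4 trials, 2 movements) for fast unit tests."""
    return SimulationConfig(
        n_movements=2,
        reps_per_movement=2,
        rest_s=2.0,
        trigger_levels_mV=(15.0, 20.0),
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config)


@pytest.fixture(scope="session")
def default_session():
    """One full-protocol session (6 movements x 10 reps), shared across tests."""
    return generate_session(SimulationConfig(rng_seed=1))


def sine(freq, rate, duration, amplitude=1.0, phase=0.0):
    t = np.arange(int(round(duration * rate))) / rate
    return amplitude * np.sin(2 * np.pi * freq * t + phase)


def fitted_amplitude(x, freq, rate):
    """Least-squares amplitude of a known-frequency sine in x."""
    t = np.arange(x.size) / rate
    design = np.column_stack(
        [np.sin(2 * np.pi * freq * t), np.cos(2 * np.pi * freq * t)]
    )
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return float(np.hypot(*coef))
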