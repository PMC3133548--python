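import numpy as np
import pytest

from nirstrial import synthgen

QUIET = dict(white_noise_sd=0.0, intensity_noise_sd=0.0, drift_slope=0.0,
             osc_components=())


@pytest.fixture
def default_config():
    return synthgen.GeneratorConfig(seed=1234)


@pytest.fixture
def quiet_config():
    """Default protocol with every noise source off."""
    return synthgen.GeneratorConfig(seed=1234, **QUIET)


@pytest.fixture
def small_config():
    """Reduced protocol for Monte-Carlo loops (50 Hz, 6 trials/condition)."""
    return synthgen.GeneratorConfig(seed=99, sampling_rate=50.0,
                                    n_trials_per_condition=6)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
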