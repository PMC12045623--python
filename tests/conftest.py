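import numpy as np
import pytest

from neurorbit import synth


@pytest.fixture(scope="session")
def pure_specs():
    """Small mixed ground-truth population: 6 units of each pure kind."""
    rng = np.random.default_rng(0)
    return synth.default_population_spec(6, rng)


@pytest.fixture(scope="session")
def noiseless_session(pure_specs):
    """Noiseless synthetic session: rates equal the tuning-model means."""
    return synth.generate_noisy_session(pure_specs, trials_per_cell=12, noise=0.0, seed=1)


EXPECTED_FLAGS = {
    "gain": (False, True, False),
    "pd_shift": (True, False, False),
    "additive": (False, False, True),
}
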