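import numpy as np
import pytest

import scnp


@pytest.fixture(scope="session")
def small_config():
    return scnp.SimulationConfig(n_patients=12, mean_events_per_well=1200,
                                 seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """One small simulated cohort shared across tests (read-only)."""
    return scnp.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def node_panel():
    return scnp.load_default_panel()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
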