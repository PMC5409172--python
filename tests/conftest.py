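import numpy as np
import pytest

from aucme.simulation import SimulationConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def model_i_dataset():
    """One fixed Model I dataset (m = n = 100, two replicates)."""
    cfg = SimulationConfig(model="I", mu_x=1.0)
    return generate_dataset(cfg, np.random.SeedSequence([105, 0, 0]))
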