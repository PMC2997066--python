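import numpy as np
import pandas as pd
import pytest

from kinact import SimulationConfig, simulate_expression, simulate_ontology


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=40,
        n_tissues=10,
        samples_per_tissue=10,
        n_modules=2,
        module_size=5,
        n_terms=7,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return simulate_expression(tiny_config)


@pytest.fixture(scope="session")
def tiny_ontology(tiny_config):
    return simulate_ontology(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20251201)


@pytest.fixture()
def small_activity() -> pd.DataFrame:
    """Hand-written 6-gene x 4-tissue binary activity matrix."""
    data = {
        "healthy_00": [1, 1, 0, 0, 1, 0],
        "healthy_01": [1, 1, 0, 0, 0, 0],
        "malignant_00": [0, 1, 1, 1, 1, 0],
        "malignant_01": [0, 1, 1, 1, 0, 1],
    }
    return pd.DataFrame(data, index=[f"g{i}" for i in range(6)])
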