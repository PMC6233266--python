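import numpy as np
import pytest

from coreg_ir.synthetic_data import SimulationConfig, generate_annotation, generate_truth


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=200, n_replicates=3, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_truth(small_config)


@pytest.fixture(scope="session")
def small_annotation(small_config):
    ann, genome = generate_annotation(small_config)
    return ann, genome


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
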