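import numpy as np
import pytest

import gsabench as gb


@pytest.fixture(scope="session")
def pool():
    """Mid-sized synthetic NB parameter pool shared across tests."""
    return gb.generate_parameter_pool(2000, seed=11)


@pytest.fixture(scope="session")
def null_dataset(pool):
    """Small H0 dataset: 5 sets of 8 genes, 5 + 5 samples."""
    return gb.simulate_null_dataset(pool, N=10, p=8, S=5, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
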