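import numpy as np
import pytest

from odorspace import SynthSpec, gen_perceptual_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_matrix():
    """A ~200-molecule synthetic perceptual matrix shared across tests."""
    A, mol_comm, desc_comm = gen_perceptual_matrix(
        SynthSpec(m=200, p=60, target_sparseness_pct=94.0, n_communities=4, seed=7)
    )
    return A, mol_comm, desc_comm
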