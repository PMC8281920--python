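import numpy as np
import pytest

from aspholib.synthetic import make_pseudo_protein


@pytest.fixture(scope="session")
def pseudo_protein():
    """A small pseudo-protein with a linear B-factor law (shared, read-only)."""
    return make_pseudo_protein(14, seed=3, law_seed=0)


@pytest.fixture(scope="session")
def structure(pseudo_protein):
    return pseudo_protein.structure


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
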