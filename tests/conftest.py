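import numpy as np
import pytest

from clonedrop import gain_chain_model, loh_chain_model


@pytest.fixture
def loh_model():
    """Chain: germline -> heterozygous mutant -> wild-type allele lost."""
    return loh_chain_model()


@pytest.fixture
def gain_model():
    """Chain: germline -> heterozygous mutant -> extra mutant copy."""
    return gain_chain_model()


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_913)
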