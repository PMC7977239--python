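import numpy as np
import pytest

from molfinder.fixtures import druglike_smiles


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def drugs():
    """The embedded drug-like fixture set, canonicalized."""
    return druglike_smiles()
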