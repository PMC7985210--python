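import warnings

import numpy as np
import pandas as pd
import pytest

from krasnet.codon_spectrum import CHANNEL_LABELS
from krasnet.signatures import SignatureCatalog

warnings.filterwarnings("ignore", message="Maximum number of iterations")


@pytest.fixture(scope="session")
def orthogonal_catalog() -> SignatureCatalog:
    """Three signatures with disjoint channel support (exactly separable)."""
    rng = np.random.default_rng(42)
    w = np.zeros((3, 96))
    w[0, :32] = rng.random(32)
    w[1, 32:64] = rng.random(32)
    w[2, 64:] = rng.random(32)
    return SignatureCatalog.from_array(w)


@pytest.fixture(scope="session")
def broad_catalog() -> SignatureCatalog:
    """Four random signatures with broad support over the 96 channels."""
    rng = np.random.default_rng(11)
    w = rng.dirichlet(np.full(96, 0.3), size=4)
    return SignatureCatalog.from_array(w)


@pytest.fixture()
def channel_frame():
    def make(values, index):
        return pd.DataFrame(values, index=index, columns=list(CHANNEL_LABELS))

    return make
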