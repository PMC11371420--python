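import numpy as np
import pytest

from conesect import (
    SpectralAxis,
    default_axis,
    make_fundamentals,
    make_observer_triple,
)


@pytest.fixture(scope="session")
def axis() -> SpectralAxis:
    return default_axis()


@pytest.fixture(scope="session")
def truth(axis):
    """Synthetic ground-truth L, M, S fundamentals on the default grid."""
    return make_fundamentals()


@pytest.fixture(scope="session")
def noiseless_triple(truth):
    """Protan/deutan/tritan CMFs with random mixings and no noise."""
    return make_observer_triple(truth, noise_sd=0.0, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1729)
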