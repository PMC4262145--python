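import numpy as np
import pytest

from rotas import build
from rotas.fixtures import helix

TRAIN_SEQUENCES = [
    "ASKLDEVFRMA", "TGNQHWYCPIL", "AEKLSDVFRMA", "MSTAILKEVDR",
    "QWERTYIPASD", "FGHKLCVNMAS",
]


@pytest.fixture(scope="session")
def helix_models():
    return [helix(s, identifier=f"h{i}") for i, s in enumerate(TRAIN_SEQUENCES)]


@pytest.fixture(scope="session")
def small_tables(helix_models):
    """Potential trained on a small varied helix set (shared, read-only)."""
    return build(helix_models)


@pytest.fixture()
def rng():
    return np.random.default_rng(20140918)
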