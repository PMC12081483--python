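import numpy as np
import pytest

from flavodesc import io as fio
from flavodesc.synthetic import gen_toy_molecules


@pytest.fixture(scope="session")
def published_orbitals():
    return fio.load_published_orbitals()


@pytest.fixture(scope="session")
def published_panel():
    return fio.load_published_panel()


@pytest.fixture(scope="session")
def toy_molecules():
    return gen_toy_molecules()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
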