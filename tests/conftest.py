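import numpy as np
import pytest

from smaup import rook_lattice


@pytest.fixture(scope="session")
def lat55():
    return rook_lattice(5, 5)


@pytest.fixture(scope="session")
def lat1010():
    return rook_lattice(10, 10)


@pytest.fixture(scope="session")
def lat3030():
    return rook_lattice(30, 30)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260917)
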