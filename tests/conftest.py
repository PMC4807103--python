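import numpy as np
import pytest

from erpfield.headmodel import HeadModel
from erpfield.montage import build_montage
from erpfield.sourcespace import build_source_grid, compute_lead_field


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def montage110():
    return build_montage(110)


@pytest.fixture(scope="session")
def montage32():
    return build_montage(32)


@pytest.fixture(scope="session")
def grid1000(head):
    return build_source_grid(head, 1000)


@pytest.fixture(scope="session")
def lead110(grid1000, montage110, head):
    return compute_lead_field(grid1000, montage110, head)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
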