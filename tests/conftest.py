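import numpy as np
import pytest

from symbond.building_blocks import (
    AttachmentFrame,
    make_toy_bonding_module,
    make_toy_cyclic_oligomer,
)


@pytest.fixture(scope="session")
def toy_c3():
    return make_toy_cyclic_oligomer(3, seed=1)


@pytest.fixture(scope="session")
def toy_c2():
    return make_toy_cyclic_oligomer(2, seed=2)


@pytest.fixture(scope="session")
def toy_c4():
    return make_toy_cyclic_oligomer(4, seed=3)


@pytest.fixture(scope="session")
def toy_module():
    return make_toy_bonding_module()


@pytest.fixture(scope="session")
def outer_frame():
    """Attachment frame outside the toy ring, safe from graft clashes."""
    return AttachmentFrame(origin=np.array([25.0, 0.0, 0.0]), basis=np.eye(3))
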