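import numpy as np
import pytest

from conscious_agents import make_fixture, two_agent_chain
from conscious_agents.asymptotics import find_absorbing_structure


@pytest.fixture(scope="session")
def identity_pair():
    return make_fixture("identity_pair")


@pytest.fixture(scope="session")
def swap_pair():
    return make_fixture("swap_d1_pair")


@pytest.fixture(scope="session")
def identity_chain(identity_pair):
    return two_agent_chain(*identity_pair)


@pytest.fixture(scope="session")
def swap_chain(swap_pair):
    return two_agent_chain(*swap_pair)


@pytest.fixture(scope="session")
def identity_struct(identity_chain):
    return find_absorbing_structure(identity_chain)


@pytest.fixture(scope="session")
def swap_struct(swap_chain):
    return find_absorbing_structure(swap_chain)


def ket(label, spaces=None):
    """Component tuple from a compact ket string like '0001'."""
    return tuple(label.replace("|", "").replace(">", ""))
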