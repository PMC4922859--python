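import numpy as np
import pytest

from rdscreen import NetworkGraph, Topology, make_nodes


@pytest.fixture
def two_node_net():
    """The completely connected two-reactant network (k = 4)."""
    nodes = make_nodes([True, True], ["v", "w"])
    return NetworkGraph(nodes, frozenset({(0, 0), (0, 1), (1, 0), (1, 1)}))


@pytest.fixture
def activator_inhibitor(two_node_net):
    """Self-enhancing activator v, feedback inhibitor w: in-phase patterns."""
    return Topology(two_node_net, {(0, 0): +1, (0, 1): -1, (1, 0): +1, (1, 1): -1})


@pytest.fixture
def substrate_depleted(two_node_net):
    """Substrate-depletion signs: out-of-phase patterns."""
    return Topology(two_node_net, {(0, 0): +1, (0, 1): +1, (1, 0): -1, (1, 1): -1})


@pytest.fixture
def three_nodes():
    return make_nodes([True, True, False], ["v", "w", "u"])


@pytest.fixture
def ai_jacobian():
    """Classical two-node Turing Jacobian; unstable iff d2/d1 > 4 + 2*sqrt(3)."""
    return np.array([[1.0, -1.0], [3.0, -2.0]])


@pytest.fixture
def capacitor_system():
    from rdscreen import fixture

    return fixture("type3_capacitor")
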