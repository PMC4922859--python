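"""Network enumeration, graph filters and canonicalisation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rdscreen import (
    NetworkGraph,
    canonical_key,
    count_networks,
    dedup_networks,
    enumerate_networks,
    make_nodes,
    passes_connectivity_filter,
)
from rdscreen.netspace import class_preserving_permutations


@pytest.mark.parametrize(
    "n, k, expected",
    [(3, 6, 84), (2, 4, 1), (4, 7, 11440)],
)
def test_count_networks_closed_form(n, k, expected):
    assert count_networks(n, k) == expected


def test_count_networks_rejects_out_of_range_k():
    with pytest.raises(ValueError, match="N\\*N = 9"):
        count_networks(3, 10)
    with pytest.raises(ValueError):
        count_networks(3, 0)


@pytest.mark.parametrize("n, k", [(2, 2), (2, 4), (3, 4), (3, 6)])
def test_enumeration_matches_closed_form(n, k):
    nodes = make_nodes([True] * n)
    nets = list(enumerate_networks(nodes, k))
    assert len(nets) == count_networks(n, k)
    assert len({net.edges for net in nets}) == len(nets)  # each exactly once


def test_enumeration_respects_forced_and_forbidden(three_nodes):
    forced = {(0, 1), (1, 0)}
    forbidden = {(2, 2)}
    nets = list(enumerate_networks(three_nodes, 4, forced, forbidden))
    for net in nets:
        assert forced <= net.edges
        assert (2, 2) not in net.edges
    # choose 2 free cells among 9 - 2 forced - 1 forbidden = 6
    assert len(nets) == 15


def test_enumeration_forbidden_diagonal_forces_unique_graph(three_nodes):
    nets = list(enumerate_networks(three_nodes, 6, forbidden_edges={(0, 0), (1, 1), (2, 2)}))
    assert len(nets) == 1
    assert all(i != j for (i, j) in nets[0].edges)


def test_infeasible_enumeration_yields_empty_stream(three_nodes, caplog):
    with caplog.at_level("WARNING"):
        nets = list(enumerate_networks(three_nodes, 2, forced_edges={(0, 1), (1, 0), (2, 0)}))
    assert nets == []
    assert any("infeasible" in rec.message for rec in caplog.records)


def test_forced_forbidden_overlap_rejected(three_nodes):
    with pytest.raises(ValueError, match="disjoint"):
        list(enumerate_networks(three_nodes, 3, {(0, 1)}, {(0, 1)}))


def test_complete_two_node_network_is_strongly_connected(two_node_net):
    assert passes_connectivity_filter(two_node_net)


def test_read_out_node_fails_connectivity(three_nodes):
    # node 2 has only incoming edges: a pure read-out
    net = NetworkGraph(three_nodes, frozenset({(0, 1), (1, 0), (2, 0), (2, 1), (0, 0), (2, 2)}))
    assert not passes_connectivity_filter(net)


def test_self_loops_do_not_create_connectivity(three_nodes):
    net = NetworkGraph(three_nodes, frozenset({(0, 0), (1, 1), (2, 2), (0, 1), (1, 0)}))
    assert not passes_connectivity_filter(net)


def _three_node_pipeline():
    nodes = make_nodes([True, True, False])
    nets = list(enumerate_networks(nodes, 6))
    sc = [n for n in nets if passes_connectivity_filter(n)]
    return nets, sc


def test_three_node_connectivity_and_dedup_counts():
    nets, sc = _three_node_pipeline()
    assert len(nets) == 84
    assert len(sc) == 48
    assert len(dedup_networks(sc)) == 25


def test_filters_are_monotone_and_dedup_idempotent():
    nets, sc = _three_node_pipeline()
    assert {n.edges for n in sc} <= {n.edges for n in nets}
    classes = dedup_networks(sc)
    assert {n.edges for n in classes} <= {n.edges for n in sc}
    again = dedup_networks(classes)
    assert [n.edges for n in again] == [n.edges for n in classes]


def test_swap_of_diffusible_nodes_preserves_key(three_nodes):
    net = NetworkGraph(three_nodes, frozenset({(0, 0), (0, 2), (1, 2), (2, 0), (2, 1), (0, 1)}))
    swapped = NetworkGraph(
        three_nodes, frozenset({(1, 1), (1, 2), (0, 2), (2, 1), (2, 0), (1, 0)})
    )
    assert canonical_key(net) == canonical_key(swapped)


@settings(max_examples=200, deadline=None)
@given(data=st.data())
def test_canonical_key_invariant_under_class_preserving_permutations(data):
    n = data.draw(st.integers(2, 4))
    flags = data.draw(
        st.lists(st.booleans(), min_size=n, max_size=n).filter(lambda f: sum(f) >= 1)
    )
    nodes = make_nodes(flags)
    cells = [(i, j) for i in range(n) for j in range(n)]
    k = data.draw(st.integers(1, min(6, len(cells))))
    edges = frozenset(data.draw(st.permutations(cells))[:k])
    net = NetworkGraph(nodes, edges)
    perms = class_preserving_permutations(nodes)
    perm = data.draw(st.sampled_from(perms))
    permuted = NetworkGraph(nodes, frozenset((perm[i], perm[j]) for (i, j) in edges))
    assert canonical_key(net) == canonical_key(permuted)


def test_edge_list_round_trip(three_nodes):
    net = NetworkGraph(three_nodes, frozenset({(0, 1), (1, 2), (2, 0), (1, 1)}))
    text = net.to_edge_list_text()
    assert "1<-2" in text.splitlines()
    back = NetworkGraph.from_edge_list_text(text, three_nodes)
    assert back.edges == net.edges


def test_graphml_and_dot_export(tmp_path, two_node_net):
    two_node_net.write_graphml(tmp_path / "net.graphml")
    two_node_net.write_dot(tmp_path / "net.dot")
    import networkx as nx

    g = nx.read_graphml(tmp_path / "net.graphml")
    assert len(g.nodes) == 2
    assert {d["diffusible"] for _, d in g.nodes(data=True)} == {True}
    assert "digraph" in (tmp_path / "net.dot").read_text()
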