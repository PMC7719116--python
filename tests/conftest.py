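from __future__ import annotations

import pytest

from hypercurv import DirectedGraph, DirectedHypergraph, UndirectedGraph, fixture


def structure_edges(s):
    """Uniform edge iterator: tuples for graphs, ids for hypergraphs."""
    if isinstance(s, DirectedHypergraph):
        return [e.id for e in s.hyperedges]
    return s.edges


@pytest.fixture
def fig3():
    return fixture("fig3")


@pytest.fixture
def k3():
    return UndirectedGraph(vertices=["a", "b", "c"], edges=[("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def p4():
    return UndirectedGraph(
        vertices=["a", "b", "c", "d"], edges=[("a", "b"), ("b", "c"), ("c", "d")]
    )


@pytest.fixture
def star_k14():
    return UndirectedGraph(
        vertices=["c", "l1", "l2", "l3", "l4"],
        edges=[("c", "l1"), ("c", "l2"), ("c", "l3"), ("c", "l4")],
    )


@pytest.fixture
def in_out_star():
    # a,b,c feed v; v -> w; w feeds x and y
    return DirectedGraph(
        vertices=["a", "b", "c", "v", "w", "x", "y"],
        edges=[("a", "v"), ("b", "v"), ("c", "v"), ("v", "w"), ("w", "x"), ("w", "y")],
    )
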