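"""Core network structures: undirected graphs, digraphs, directed hypergraphs.

The directed hypergraph is the central object: a hyperedge is an ordered pair
of vertex subsets (tail ``e1``, head ``e2``), the natural model of a chemical
reaction (reactants -> products).  Plain graphs are special cases — an
undirected edge is a symmetric pairwise relation, a directed edge a hyperedge
with singleton tail and head — and :func:`digraph_to_hypergraph` makes that
embedding explicit so every directed measure has a single code path.

Vertex labels are opaque strings compared by exact equality (metabolite ids
like ``"h"`` and ``"h2o"`` are distinct labels, nothing more).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import networkx as nx

__all__ = [
    "GraphError",
    "UndirectedGraph",
    "DirectedGraph",
    "DirectedHyperedge",
    "DirectedHypergraph",
    "edges_at",
    "in_hyperedges_at",
    "out_hyperedges_at",
    "digraph_to_hypergraph",
]


class GraphError(ValueError):
    """Structural violation: unknown vertex, self-loop, duplicate id, ..."""


def _check_label(v: object) -> str:
    if not isinstance(v, str) or not v:
        raise GraphError(f"vertex labels must be non-empty strings, got {v!r}")
    return v


class UndirectedGraph:
    """Simple undirected graph: no self-loops, no parallel edges.

    Edges are stored canonically as sorted 2-tuples of labels; adding the
    same unordered pair twice is idempotent.  Backed by :class:`networkx.Graph`
    for adjacency and shortest-path queries.
    """

    def __init__(self, vertices: Iterable[str] = (), edges: Iterable[tuple[str, str]] = ()):
        self._g = nx.Graph()
        for v in vertices:
            self.add_vertex(v)
        for v, w in edges:
            self.add_edge(v, w)

    def add_vertex(self, v: str) -> None:
        self._g.add_node(_check_label(v))

    def add_edge(self, v: str, w: str) -> None:
        _check_label(v), _check_label(w)
        if v == w:
            raise GraphError(f"self-loop at {v!r} not allowed")
        self._g.add_edge(v, w)

    @property
    def vertices(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        """Edges in insertion order, each as a sorted tuple."""
        return [self.canonical(v, w) for v, w in self._g.edges]

    @staticmethod
    def canonical(v: str, w: str) -> tuple[str, str]:
        return (v, w) if v <= w else (w, v)

    def has_vertex(self, v: str) -> bool:
        return v in self._g

    def has_edge(self, v: str, w: str) -> bool:
        return self._g.has_edge(v, w)

    def degree(self, v: str) -> int:
        self._require(v)
        return self._g.degree(v)

    def neighbors(self, v: str) -> list[str]:
        self._require(v)
        return list(self._g.neighbors(v))

    def _require(self, v: str) -> None:
        if v not in self._g:
            raise GraphError(f"unknown vertex {v!r}")

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __repr__(self) -> str:
        return f"UndirectedGraph({self._g.number_of_nodes()} vertices, {self._g.number_of_edges()} edges)"


class DirectedGraph:
    """Simple directed graph: no self-loops; at most one edge per ordered
    pair, but (a,b) and (b,a) may coexist."""

    def __init__(self, vertices: Iterable[str] = (), edges: Iterable[tuple[str, str]] = ()):
        self._g = nx.DiGraph()
        for v in vertices:
            self.add_vertex(v)
        for v, w in edges:
            self.add_edge(v, w)

    def add_vertex(self, v: str) -> None:
        self._g.add_node(_check_label(v))

    def add_edge(self, tail: str, head: str) -> None:
        _check_label(tail), _check_label(head)
        if tail == head:
            raise GraphError(f"self-loop at {tail!r} not allowed")
        self._g.add_edge(tail, head)

    @property
    def vertices(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self._g.edges)

    def has_vertex(self, v: str) -> bool:
        return v in self._g

    def has_edge(self, tail: str, head: str) -> bool:
        return self._g.has_edge(tail, head)

    def in_degree(self, v: str) -> int:
        self._require(v)
        return self._g.in_degree(v)

    def out_degree(self, v: str) -> int:
        self._require(v)
        return self._g.out_degree(v)

    def _require(self, v: str) -> None:
        if v not in self._g:
            raise GraphError(f"unknown vertex {v!r}")

    def to_networkx(self) -> nx.DiGraph:
        return self._g.copy()

    def __repr__(self) -> str:
        return f"DirectedGraph({self._g.number_of_nodes()} vertices, {self._g.number_of_edges()} edges)"


@dataclass(frozen=True)
class DirectedHyperedge:
    """Ordered pair of vertex subsets: ``tail`` (inputs, e1) -> ``head``
    (outputs, e2).  Tail and head may overlap (catalysts); at most one side
    may be empty."""

    id: str
    tail: frozenset[str]
    head: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "tail", frozenset(self.tail))
        object.__setattr__(self, "head", frozenset(self.head))
        _check_label(self.id)
        if not self.tail and not self.head:
            raise GraphError(f"hyperedge {self.id!r}: tail and head cannot both be empty")

    def __repr__(self) -> str:
        t = ",".join(sorted(self.tail))
        h = ",".join(sorted(self.head))
        return f"DirectedHyperedge({self.id!r}: {{{t}}} -> {{{h}}})"


class DirectedHypergraph:
    """Directed hypergraph H = (V, E): hyperedges are ordered pairs of vertex
    subsets with unique ids.  Parallel hyperedges (identical tail/head under
    distinct ids) are allowed; ids distinguish them."""

    def __init__(self, vertices: Iterable[str] = (), hyperedges: Iterable[DirectedHyperedge] = ()):
        self._vertices: dict[str, None] = {}
        self._edges: dict[str, DirectedHyperedge] = {}
        # vertex -> ids of hyperedges having it in head / tail, insertion order
        self._in_index: dict[str, list[str]] = {}
        self._out_index: dict[str, list[str]] = {}
        for v in vertices:
            self.add_vertex(v)
        for e in hyperedges:
            self.add_hyperedge(e)

    def add_vertex(self, v: str) -> None:
        self._vertices.setdefault(_check_label(v), None)
        self._in_index.setdefault(v, [])
        self._out_index.setdefault(v, [])

    def add_hyperedge(self, e: DirectedHyperedge) -> None:
        if e.id in self._edges:
            raise GraphError(f"duplicate hyperedge id {e.id!r}")
        for v in e.tail | e.head:
            if v not in self._vertices:
                raise GraphError(f"hyperedge {e.id!r} references undeclared vertex {v!r}")
        self._edges[e.id] = e
        for v in e.tail:
            self._out_index[v].append(e.id)
        for v in e.head:
            self._in_index[v].append(e.id)

    @property
    def vertices(self) -> frozenset[str]:
        return frozenset(self._vertices)

    @property
    def hyperedges(self) -> list[DirectedHyperedge]:
        return list(self._edges.values())

    def hyperedge(self, eid: str) -> DirectedHyperedge:
        try:
            return self._edges[eid]
        except KeyError:
            raise GraphError(f"unknown hyperedge id {eid!r}") from None

    def has_vertex(self, v: str) -> bool:
        return v in self._vertices

    def has_hyperedge(self, eid: str) -> bool:
        return eid in self._edges

    def _require(self, v: str) -> None:
        if v not in self._vertices:
            raise GraphError(f"unknown vertex {v!r}")

    def successors(self, v: str) -> set[str]:
        """Vertices reachable from v in one hyperedge step (v in tail -> head)."""
        self._require(v)
        out: set[str] = set()
        for eid in self._out_index[v]:
            out |= self._edges[eid].head
        return out

    def __repr__(self) -> str:
        return f"DirectedHypergraph({len(self._vertices)} vertices, {len(self._edges)} hyperedges)"


def edges_at(graph: UndirectedGraph, v: str) -> set[tuple[str, str]]:
    """E_v: the set of edges incident to ``v`` (canonical tuples).

    For an edge e = (v, w) the returned set contains e itself.
    """
    graph._require(v)
    return {graph.canonical(v, w) for w in graph.neighbors(v)}


def in_hyperedges_at(
    H: DirectedHypergraph, v: str, exclude: Optional[str] = None
) -> list[DirectedHyperedge]:
    """Hyperedges coming in at ``v`` (those with v in their head), in
    insertion order, minus the hyperedge id ``exclude`` if given."""
    H._require(v)
    return [H._edges[eid] for eid in H._in_index[v] if eid != exclude]


def out_hyperedges_at(
    H: DirectedHypergraph, v: str, exclude: Optional[str] = None
) -> list[DirectedHyperedge]:
    """Hyperedges going out at ``v`` (those with v in their tail)."""
    H._require(v)
    return [H._edges[eid] for eid in H._out_index[v] if eid != exclude]


def digraph_edge_id(tail: str, head: str) -> str:
    return f"{tail}->{head}"


def digraph_to_hypergraph(D: DirectedGraph) -> DirectedHypergraph:
    """Embed a digraph as a hypergraph: each edge (v, w) becomes a hyperedge
    with tail {v} and head {w}, id ``"v->w"``.  Vertex set is preserved.

    Curvature measures computed on the image agree with the directed-graph
    definitions edge for edge; this is the bridge that lets graphs and
    hypergraphs share one optimal-transport code path.
    """
    H = DirectedHypergraph(vertices=sorted(D.vertices))
    for v, w in D.edges:
        H.add_hyperedge(DirectedHyperedge(digraph_edge_id(v, w), frozenset({v}), frozenset({w})))
    return H
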