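"""Combinatorial edge curvature: Forman-Ricci curvature and degree difference.

Forman-Ricci curvature of an edge counts how many other (hyper)edges crowd
around it: F(e) = 2 - deg(e) for a graph edge, where deg(e) is the number of
neighbouring edges (an edge is not its own neighbour), and
F(e) = |e1| + |e2| - deg_in(e) - deg_out(e) for a directed hyperedge, where
incoming hyperedges are counted once per tail vertex of e they feed
(multiplicity counting), and symmetrically for outgoing ones.  Very negative
F marks edges whose endpoints are hubs.

The degree difference daleth(e) is |deg_v(e) - deg_w(e)| for an undirected
edge, and the signed deg_out(e) - deg_in(e) for directed edges and
hyperedges: positive for "productive" relations that emit more than they
receive, negative for "receptive" ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Union

from .model import (
    DirectedGraph,
    DirectedHyperedge,
    DirectedHypergraph,
    GraphError,
    UndirectedGraph,
    edges_at,
    in_hyperedges_at,
    out_hyperedges_at,
)

__all__ = [
    "CurvatureRecord",
    "forman_undirected",
    "forman_directed",
    "forman_hypergraph",
    "hypergraph_degrees",
    "degree_difference",
    "forman",
]

Number = Union[int, float, Fraction]


@dataclass
class CurvatureRecord:
    """Per-(hyper)edge curvature results; ollivier/m_vector are None when the
    transport computation was not requested."""

    edge_id: str
    forman: Optional[int] = None
    degree_difference: Optional[int] = None
    ollivier: Optional[Number] = None
    m_vector: Optional[tuple[Number, Number, Number, Number]] = None


def _require_undirected_edge(G: UndirectedGraph, e: tuple[str, str]) -> tuple[str, str]:
    v, w = e
    if not (G.has_vertex(v) and G.has_vertex(w) and G.has_edge(v, w)):
        raise GraphError(f"edge {e!r} not in graph")
    return v, w


def _require_directed_edge(D: DirectedGraph, e: tuple[str, str]) -> tuple[str, str]:
    v, w = e
    if not (D.has_vertex(v) and D.has_vertex(w) and D.has_edge(v, w)):
        raise GraphError(f"directed edge {e!r} not in graph")
    return v, w


def _resolve_hyperedge(H: DirectedHypergraph, e: Union[str, DirectedHyperedge]) -> DirectedHyperedge:
    eid = e if isinstance(e, str) else e.id
    he = H.hyperedge(eid)
    if not isinstance(e, str) and (he.tail != e.tail or he.head != e.head):
        raise GraphError(f"hyperedge {eid!r} differs from the one stored in the hypergraph")
    return he


def forman_undirected(G: UndirectedGraph, e: tuple[str, str]) -> int:
    """F(e) = 2 - #(neighbours of e); neighbours share a vertex with e."""
    v, w = _require_undirected_edge(G, e)
    neighbours = (edges_at(G, v) | edges_at(G, w)) - {G.canonical(v, w)}
    return 2 - len(neighbours)


def forman_directed(D: DirectedGraph, e: tuple[str, str]) -> int:
    """F_dir(e) = 2 - deg_in(e) - deg_out(e) for e = (v, w): deg_in counts
    edges with head v, deg_out edges with tail w.  The reverse edge (w, v),
    when present, contributes to both counts — the definition is purely
    incidence-based."""
    v, w = _require_directed_edge(D, e)
    return 2 - D.in_degree(v) - D.out_degree(w)


def hypergraph_degrees(H: DirectedHypergraph, e: Union[str, DirectedHyperedge]) -> tuple[int, int]:
    """(deg_in, deg_out) of a hyperedge with multiplicity counting: an
    incoming hyperedge is counted once per tail vertex of e in its head.
    The focal hyperedge never counts itself, even when tail and head overlap."""
    he = _resolve_hyperedge(H, e)
    deg_in = sum(len(in_hyperedges_at(H, v, exclude=he.id)) for v in he.tail)
    deg_out = sum(len(out_hyperedges_at(H, v, exclude=he.id)) for v in he.head)
    return deg_in, deg_out


def forman_hypergraph(H: DirectedHypergraph, e: Union[str, DirectedHyperedge]) -> int:
    """F_dir(e) = |e1| + |e2| - deg_in(e) - deg_out(e)."""
    he = _resolve_hyperedge(H, e)
    deg_in, deg_out = hypergraph_degrees(H, he)
    return len(he.tail) + len(he.head) - deg_in - deg_out


def degree_difference(structure, e) -> int:
    """daleth(e): |deg_v - deg_w| (undirected) or deg_out - deg_in (directed
    graph / hypergraph, signed)."""
    if isinstance(structure, UndirectedGraph):
        v, w = _require_undirected_edge(structure, e)
        # deg_v(e) = edges sharing v with e, excluding e itself
        return abs((structure.degree(v) - 1) - (structure.degree(w) - 1))
    if isinstance(structure, DirectedGraph):
        v, w = _require_directed_edge(structure, e)
        return structure.out_degree(w) - structure.in_degree(v)
    if isinstance(structure, DirectedHypergraph):
        deg_in, deg_out = hypergraph_degrees(structure, e)
        return deg_out - deg_in
    raise TypeError(f"unsupported structure {type(structure).__name__}")


def forman(structure, e) -> int:
    """Dispatch to the Forman-Ricci variant matching the structure type."""
    if isinstance(structure, UndirectedGraph):
        return forman_undirected(structure, e)
    if isinstance(structure, DirectedGraph):
        return forman_directed(structure, e)
    if isinstance(structure, DirectedHypergraph):
        return forman_hypergraph(structure, e)
    raise TypeError(f"unsupported structure {type(structure).__name__}")
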