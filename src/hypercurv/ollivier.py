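"""Ollivier-Ricci curvature via exact optimal transport.

An edge carries two probability measures — what feeds it and what it feeds —
and its Ollivier-Ricci curvature is O(e) = 1 - W1(mu_in, mu_out), the
1-Wasserstein (earth-mover) cost of rearranging the input measure onto the
output measure along network distances.  Equivalently, if m_i is the mass an
optimal plan moves at distance i, O(e) = m0 - m2 - 2*m3: coincidences
(directed triangles) push curvature up, long detours push it down.  Mass
never needs to travel farther than 3, because the route through e itself
(input vertex -> tail, tail -> head through e, head -> output vertex) always
exists; hence O(e) is bounded in [-2, 1].

Measure construction for a directed hyperedge e = (e1, e2) follows an
even-splitting cascade: each of the eta_in tail vertices starts with
1/eta_in; a source (tail vertex with no other incoming hyperedge) keeps its
share in place, otherwise the share is split evenly over the incoming
hyperedges at that vertex and then evenly over each such hyperedge's tail
vertices (the "masses").  The out-measure mirrors this on the head side
(sinks and "holes").  All weights are exact rationals.

Undirected edges use the neighbour measures: mu_v is uniform over the far
endpoints of the edges at v (including e's own far endpoint w), and the
ground distance is the unrestricted shortest-path distance in the graph.
Directed graphs are routed through their hypergraph embedding, which
reproduces the classical directed definition edge for edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Mapping, Optional, Union

import networkx as nx
import numpy as np
import scipy.sparse
from scipy.optimize import linprog

from .model import (
    DirectedGraph,
    DirectedHyperedge,
    DirectedHypergraph,
    GraphError,
    UndirectedGraph,
    digraph_edge_id,
    digraph_to_hypergraph,
    edges_at,
    in_hyperedges_at,
    out_hyperedges_at,
)
from .forman import _require_undirected_edge, _resolve_hyperedge

__all__ = [
    "MeasureError",
    "VertexMeasure",
    "TransportPlan",
    "OllivierResult",
    "undirected_measures",
    "hyper_in_measure",
    "hyper_out_measure",
    "mass_set",
    "hole_set",
    "hyper_distance",
    "wasserstein1",
    "ollivier",
]

# exact transportation simplex is used up to this many cells; beyond it the
# float LP (HiGHS) takes over
EXACT_CELL_LIMIT = 1024

MAX_TRANSPORT_DISTANCE = 3

Number = Union[float, Fraction]


class MeasureError(ValueError):
    """Ill-posed measure construction or transport problem."""


@dataclass
class VertexMeasure:
    """Probability measure over vertices with exact rational weights.

    ``side`` records which construction produced it: "in", "out",
    "undirected-v" or "undirected-w".
    """

    entries: dict[str, Fraction]
    side: str = "in"

    def __post_init__(self):
        self.entries = {v: Fraction(w) for v, w in self.entries.items()}
        if any(w <= 0 for w in self.entries.values()):
            raise MeasureError("measure weights must be positive")
        if sum(self.entries.values(), Fraction(0)) != 1:
            raise MeasureError("measure weights must sum to exactly 1")

    @property
    def support(self) -> list[str]:
        return sorted(self.entries)

    def __getitem__(self, v: str) -> Fraction:
        return self.entries[v]


@dataclass
class TransportPlan:
    """A feasible (here: optimal) transport plan between two vertex measures.

    ``moves`` maps (source vertex, target vertex) to the mass moved;
    ``m_vector`` = (m0, m1, m2, m3) aggregates moved mass by ground distance,
    so cost = m1 + 2*m2 + 3*m3.  Optimal plans are generally non-unique: the
    cost is canonical, the m_vector is that of the returned plan.
    """

    moves: dict[tuple[str, str], Number]
    cost: Number
    m_vector: tuple[Number, Number, Number, Number]

    @property
    def exact(self) -> bool:
        return isinstance(self.cost, Fraction)


@dataclass
class OllivierResult:
    """O(e) = 1 - W1 together with the optimal plan that attained it."""

    value: Number
    m_vector: tuple[Number, Number, Number, Number]
    plan: TransportPlan
    mu_in: VertexMeasure
    mu_out: VertexMeasure

    def __iter__(self):
        # allow ``value, m_vector = ollivier(...)``
        return iter((self.value, self.m_vector))


# ---------------------------------------------------------------------------
# measure construction
# ---------------------------------------------------------------------------

def undirected_measures(
    G: UndirectedGraph, e: tuple[str, str]
) -> tuple[VertexMeasure, VertexMeasure]:
    """(mu_v, mu_w) for e = (v, w): mu_v gives weight 1/|E_v| to the far
    endpoint of every edge at v.  E_v contains e itself, so w is always in
    the support of mu_v (and v in that of mu_w)."""
    v, w = _require_undirected_edge(G, e)

    def measure(centre: str, side: str) -> VertexMeasure:
        incident = edges_at(G, centre)
        weight = Fraction(1, len(incident))
        entries = {(b if a == centre else a): weight for a, b in incident}
        return VertexMeasure(entries, side=side)

    return measure(v, "undirected-v"), measure(w, "undirected-w")


def _carriers_in(H: DirectedHypergraph, v: str, exclude: str) -> list[DirectedHyperedge]:
    # incoming hyperedges that can actually carry mass (non-empty tail)
    return [f for f in in_hyperedges_at(H, v, exclude=exclude) if f.tail]


def _carriers_out(H: DirectedHypergraph, v: str, exclude: str) -> list[DirectedHyperedge]:
    return [f for f in out_hyperedges_at(H, v, exclude=exclude) if f.head]


def hyper_in_measure(H: DirectedHypergraph, e: Union[str, DirectedHyperedge]) -> VertexMeasure:
    """mu_in of a hyperedge by the even-splitting cascade over sources and
    masses (see module docstring).  The focal hyperedge is excluded from the
    incoming lists even when its tail and head overlap."""
    he = _resolve_hyperedge(H, e)
    if not he.tail:
        raise MeasureError(f"hyperedge {he.id!r} is head-only: in-measure undefined")
    eta = len(he.tail)
    entries: dict[str, Fraction] = {}
    for t in sorted(he.tail):
        share = Fraction(1, eta)
        incoming = _carriers_in(H, t, exclude=he.id)
        if not incoming:
            entries[t] = entries.get(t, Fraction(0)) + share  # source keeps its mass
        else:
            per_edge = share / len(incoming)
            for f in incoming:
                per_vertex = per_edge / len(f.tail)
                for u in sorted(f.tail):
                    entries[u] = entries.get(u, Fraction(0)) + per_vertex
    return VertexMeasure(entries, side="in")


def hyper_out_measure(H: DirectedHypergraph, e: Union[str, DirectedHyperedge]) -> VertexMeasure:
    """mu_out: mirror image of :func:`hyper_in_measure` on the head side
    (sinks keep their share; otherwise split over outgoing hyperedges at each
    head vertex, then over their head vertices — the "holes")."""
    he = _resolve_hyperedge(H, e)
    if not he.head:
        raise MeasureError(f"hyperedge {he.id!r} is tail-only: out-measure undefined")
    eta = len(he.head)
    entries: dict[str, Fraction] = {}
    for h in sorted(he.head):
        share = Fraction(1, eta)
        outgoing = _carriers_out(H, h, exclude=he.id)
        if not outgoing:
            entries[h] = entries.get(h, Fraction(0)) + share  # sink keeps its mass
        else:
            per_edge = share / len(outgoing)
            for g in outgoing:
                per_vertex = per_edge / len(g.head)
                for u in sorted(g.head):
                    entries[u] = entries.get(u, Fraction(0)) + per_vertex
    return VertexMeasure(entries, side="out")


def mass_set(H: DirectedHypergraph, e: Union[str, DirectedHyperedge]) -> frozenset[str]:
    """The mass set M of e: union of the tails of hyperedges coming in at
    tail vertices of e (the focal hyperedge excluded).  Sources are *not*
    members of M; they are reported by the measure support instead."""
    he = _resolve_hyperedge(H, e)
    out: set[str] = set()
    for t in he.tail:
        for f in in_hyperedges_at(H, t, exclude=he.id):
            out |= f.tail
    return frozenset(out)


def hole_set(H: DirectedHypergraph, e: Union[str, DirectedHyperedge]) -> frozenset[str]:
    """The hole set of e: union of the heads of hyperedges going out at head
    vertices of e (focal hyperedge excluded)."""
    he = _resolve_hyperedge(H, e)
    out: set[str] = set()
    for h in he.head:
        for g in out_hyperedges_at(H, h, exclude=he.id):
            out |= g.head
    return frozenset(out)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def hyper_distance(
    H: DirectedHypergraph, u: str, v: str, max_depth: int = MAX_TRANSPORT_DISTANCE
) -> Optional[int]:
    """Length of the shortest directed hyperpath from u to v: one step goes
    from any tail vertex of a hyperedge to any of its head vertices.  BFS
    truncated at ``max_depth``; returns None when no path that short exists.
    0 iff u == v."""
    H._require(u)
    H._require(v)
    if u == v:
        return 0
    frontier = {u}
    seen = {u}
    for depth in range(1, max_depth + 1):
        nxt: set[str] = set()
        for x in frontier:
            nxt |= H.successors(x)
        if v in nxt:
            return depth
        nxt -= seen
        if not nxt:
            return None
        seen |= nxt
        frontier = nxt
    return None


def _hyper_distance_table(
    H: DirectedHypergraph, sources: list[str], targets: list[str]
) -> dict[tuple[str, str], int]:
    target_set = set(targets)
    table: dict[tuple[str, str], int] = {}
    for u in sources:
        remaining = set(target_set)
        if u in remaining:
            table[(u, u)] = 0
            remaining.discard(u)
        frontier = {u}
        seen = {u}
        depth = 0
        while remaining and depth < MAX_TRANSPORT_DISTANCE:
            depth += 1
            nxt: set[str] = set()
            for x in frontier:
                nxt |= H.successors(x)
            for t in remaining & nxt:
                table[(u, t)] = depth
            remaining -= nxt
            nxt -= seen
            if not nxt:
                break
            seen |= nxt
            frontier = nxt
        if remaining:
            # provably impossible between a mass and a hole of the same
            # hyperedge: the route through the hyperedge has length <= 3
            raise MeasureError(
                f"no directed hyperpath of length <= {MAX_TRANSPORT_DISTANCE} from "
                f"{u!r} to {sorted(remaining)}; inconsistent measure/support data"
            )
    return table


def _undirected_distance_table(
    G: UndirectedGraph, sources: list[str], targets: list[str]
) -> dict[tuple[str, str], int]:
    g = G._g
    target_set = set(targets)
    table: dict[tuple[str, str], int] = {}
    for u in sources:
        lengths = nx.single_source_shortest_path_length(g, u, cutoff=MAX_TRANSPORT_DISTANCE)
        for t in target_set:
            if t in lengths:
                table[(u, t)] = lengths[t]
            else:
                raise MeasureError(
                    f"vertices {u!r} and {t!r} are farther than {MAX_TRANSPORT_DISTANCE} "
                    "apart; not a neighbour pair of a common edge"
                )
    return table


# ---------------------------------------------------------------------------
# exact transportation simplex (Fractions, Bland's rule)
# ---------------------------------------------------------------------------

def _northwest_corner(supply: list[Fraction], demand: list[Fraction]):
    m, n = len(supply), len(demand)
    flow: dict[tuple[int, int], Fraction] = {}
    s, d = list(supply), list(demand)
    i = j = 0
    while True:
        q = min(s[i], d[j])
        flow[(i, j)] = q
        s[i] -= q
        d[j] -= q
        if i == m - 1 and j == n - 1:
            break
        if s[i] == 0 and i < m - 1:
            i += 1
        else:
            j += 1
    return flow  # exactly m + n - 1 basic cells (some possibly zero)


def _tree_duals(flow, m: int, n: int, cost) -> tuple[list, list]:
    u: list = [None] * m
    v: list = [None] * n
    adj_r: dict[int, list[int]] = {i: [] for i in range(m)}
    adj_c: dict[int, list[int]] = {j: [] for j in range(n)}
    for (i, j) in flow:
        adj_r[i].append(j)
        adj_c[j].append(i)
    u[0] = Fraction(0)
    stack = [("r", 0)]
    while stack:
        kind, k = stack.pop()
        if kind == "r":
            for j in adj_r[k]:
                if v[j] is None:
                    v[j] = cost[k][j] - u[k]
                    stack.append(("c", j))
        else:
            for i in adj_c[k]:
                if u[i] is None:
                    u[i] = cost[i][k] - v[k]
                    stack.append(("r", i))
    return u, v


def _tree_path(flow, start_row: int, end_col: int):
    """Path of basic cells from row node start_row to column node end_col in
    the basis spanning tree; returns the cell sequence along the path."""
    adj: dict[tuple, list[tuple]] = {}
    for (i, j) in flow:
        adj.setdefault(("r", i), []).append(("c", j))
        adj.setdefault(("c", j), []).append(("r", i))
    target = ("c", end_col)
    parent: dict[tuple, tuple] = {("r", start_row): ("r", start_row)}
    stack = [("r", start_row)]
    while stack:
        node = stack.pop()
        if node == target:
            break
        for nb in adj.get(node, ()):
            if nb not in parent:
                parent[nb] = node
                stack.append(nb)
    path_nodes = [target]
    while path_nodes[-1] != ("r", start_row):
        path_nodes.append(parent[path_nodes[-1]])
    path_nodes.reverse()
    cells = []
    for a, b in zip(path_nodes, path_nodes[1:]):
        (ka, xa), (kb, xb) = a, b
        cells.append((xa, xb) if ka == "r" else (xb, xa))
    return cells


def _transport_exact(supply: list[Fraction], demand: list[Fraction], cost):
    """Exact minimum-cost transportation over rationals.

    Classical transportation simplex on the basis spanning tree; the entering
    cell is the lexicographically first with negative reduced cost and the
    leaving cell the lexicographically smallest minimiser (Bland-style rule,
    which precludes cycling under degeneracy).  Returns (flow dict, cost).
    """
    m, n = len(supply), len(demand)
    if m == 1:
        flow = {(0, j): demand[j] for j in range(n)}
        return flow, sum((cost[0][j] * demand[j] for j in range(n)), Fraction(0))
    if n == 1:
        flow = {(i, 0): supply[i] for i in range(m)}
        return flow, sum((cost[i][0] * supply[i] for i in range(m)), Fraction(0))

    flow = _northwest_corner(supply, demand)
    while True:
        u, v = _tree_duals(flow, m, n, cost)
        entering = None
        for i in range(m):
            for j in range(n):
                if (i, j) not in flow and cost[i][j] - u[i] - v[j] < 0:
                    entering = (i, j)
                    break
            if entering:
                break
        if entering is None:
            break
        ei, ej = entering
        path = _tree_path(flow, ei, ej)
        # cycle: entering (+) then path cells reversed with alternating -,+,...
        minus_cells = []
        plus_cells = []
        for idx, cell in enumerate(reversed(path)):
            (minus_cells if idx % 2 == 0 else plus_cells).append(cell)
        theta = min(flow[c] for c in minus_cells)
        leaving = min(c for c in minus_cells if flow[c] == theta)
        for c in minus_cells:
            flow[c] -= theta
        for c in plus_cells:
            flow[c] += theta
        flow[entering] = theta
        del flow[leaving]

    total = sum((cost[i][j] * q for (i, j), q in flow.items()), Fraction(0))
    return flow, total


def _transport_lp(supply, demand, cost):
    """Float transportation LP via HiGHS; used beyond the exact-cell limit."""
    m, n = len(supply), len(demand)
    c = np.asarray(cost, dtype=float).ravel()
    rows, cols, vals = [], [], []
    for i in range(m):
        for j in range(n):
            k = i * n + j
            rows.append(i)
            cols.append(k)
            vals.append(1.0)
            rows.append(m + j)
            cols.append(k)
            vals.append(1.0)
    A = scipy.sparse.coo_matrix((vals, (rows, cols)), shape=(m + n, m * n))
    b = np.concatenate([np.asarray(supply, dtype=float), np.asarray(demand, dtype=float)])
    res = linprog(c, A_eq=A.tocsr(), b_eq=b, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - transportation LPs are always feasible
        raise MeasureError(f"transportation LP failed: {res.message}")
    x = res.x.reshape(m, n)
    x[x < 1e-15] = 0.0
    flow = {(i, j): x[i, j] for i in range(m) for j in range(n) if x[i, j] > 0}
    return flow, float(np.dot(res.x, c))


def wasserstein1(
    mu_a: VertexMeasure,
    mu_b: VertexMeasure,
    dist: Union[Mapping[tuple[str, str], int], Callable[[str, str], int]],
    method: str = "auto",
) -> TransportPlan:
    """Exact 1-Wasserstein distance between two vertex measures.

    ``dist`` gives the ground distance for every (support(mu_a) x
    support(mu_b)) pair, as a mapping or a callable; all distances must be in
    {0, 1, 2, 3}.  ``method`` is "auto" (exact rationals up to
    ``EXACT_CELL_LIMIT`` cells, float LP beyond), "exact" or "lp".
    """
    sa, sb = mu_a.support, mu_b.support
    if sum(mu_a.entries.values()) != 1 or sum(mu_b.entries.values()) != 1:
        raise MeasureError("marginals must each sum to exactly 1")
    lookup = dist if callable(dist) else lambda u, v: dist[(u, v)]
    cost = [[lookup(u, v) for v in sb] for u in sa]
    for row in cost:
        for d in row:
            if d not in (0, 1, 2, 3):
                raise MeasureError(f"ground distance {d!r} outside 0..{MAX_TRANSPORT_DISTANCE}")
    supply = [mu_a[u] for u in sa]
    demand = [mu_b[v] for v in sb]

    if method == "auto":
        method = "exact" if len(sa) * len(sb) <= EXACT_CELL_LIMIT else "lp"
    if method == "exact":
        flow, total = _transport_exact(supply, demand, cost)
        zero = Fraction(0)
    elif method == "lp":
        flow, total = _transport_lp(supply, demand, cost)
        zero = 0.0
    else:
        raise ValueError(f"unknown method {method!r}")

    moves = {(sa[i], sb[j]): q for (i, j), q in flow.items() if q > 0}
    m_vec = [zero, zero, zero, zero]
    for (i, j), q in flow.items():
        if q > 0:
            m_vec[cost[i][j]] += q
    return TransportPlan(moves=moves, cost=total, m_vector=tuple(m_vec))


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

def _ollivier_hypergraph(H: DirectedHypergraph, e) -> OllivierResult:
    he = _resolve_hyperedge(H, e)
    mu_in = hyper_in_measure(H, he)
    mu_out = hyper_out_measure(H, he)
    table = _hyper_distance_table(H, mu_in.support, mu_out.support)
    plan = wasserstein1(mu_in, mu_out, table)
    return OllivierResult(1 - plan.cost, plan.m_vector, plan, mu_in, mu_out)


def _ollivier_undirected(G: UndirectedGraph, e) -> OllivierResult:
    mu_v, mu_w = undirected_measures(G, e)
    table = _undirected_distance_table(G, mu_v.support, mu_w.support)
    plan = wasserstein1(mu_v, mu_w, table)
    return OllivierResult(1 - plan.cost, plan.m_vector, plan, mu_v, mu_w)


def ollivier(structure, e) -> OllivierResult:
    """O(e) = 1 - W1 for an edge of any supported structure, together with
    the m-vector and optimal plan.  Directed graphs are computed through
    their hypergraph embedding (identical results, one code path)."""
    if isinstance(structure, UndirectedGraph):
        return _ollivier_undirected(structure, e)
    if isinstance(structure, DirectedGraph):
        from .forman import _require_directed_edge

        v, w = _require_directed_edge(structure, e)
        H = digraph_to_hypergraph(structure)
        return _ollivier_hypergraph(H, digraph_edge_id(v, w))
    if isinstance(structure, DirectedHypergraph):
        return _ollivier_hypergraph(structure, e)
    raise TypeError(f"unsupported structure {type(structure).__name__}")
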