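"""Batch curvature computation, distribution summaries, assortativity and
giant-component extraction — the library layer behind the ``curv`` CLI."""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx
import numpy as np

from .forman import CurvatureRecord, degree_difference
from .forman import forman as _forman_dispatch
from .ollivier import ollivier as _ollivier_dispatch
from .model import (
    DirectedGraph,
    DirectedHypergraph,
    GraphError,
    UndirectedGraph,
    digraph_edge_id,
    digraph_to_hypergraph,
)

__all__ = [
    "SummaryReport",
    "ALL_MEASURES",
    "compute_all",
    "summarize",
    "degree_assortativity",
    "giant_component",
]

logger = logging.getLogger("hypercurv")

ALL_MEASURES = frozenset({"forman", "daleth", "ollivier"})
DEFAULT_BIN_WIDTH = {"forman": 1.0, "daleth": 1.0, "ollivier": 0.05}

_PROGRESS_EVERY = 1000


@dataclass
class SummaryReport:
    """Distribution summary of one measure over a set of records; histogram
    bins are contiguous, anchored at floor(min), and partition the values
    (counts sum to ``count``)."""

    measure: str
    count: int
    min: float
    max: float
    mean: float
    median: float
    histogram: list[tuple[float, float, int]]  # (lower bound, width, count)


def _edge_label(structure, e) -> str:
    if isinstance(structure, UndirectedGraph):
        return f"{e[0]}--{e[1]}"
    if isinstance(structure, DirectedGraph):
        return digraph_edge_id(*e)
    return e  # hyperedge id


def compute_all(structure, measures: Iterable[str] = ALL_MEASURES) -> list[CurvatureRecord]:
    """One CurvatureRecord per (hyper)edge, in input order.  ``measures`` is
    any subset of {"forman", "daleth", "ollivier"}; Ollivier is the costly
    one and each edge is independent of every other (any execution order
    gives identical output)."""
    measures = frozenset(measures)
    unknown = measures - ALL_MEASURES
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")

    if isinstance(structure, UndirectedGraph):
        items = structure.edges
        ollivier_target = structure
    elif isinstance(structure, DirectedGraph):
        items = structure.edges
        # one conversion for the whole batch instead of one per edge
        ollivier_target = digraph_to_hypergraph(structure) if "ollivier" in measures else None
    elif isinstance(structure, DirectedHypergraph):
        items = [e.id for e in structure.hyperedges]
        ollivier_target = structure
    else:
        raise TypeError(f"unsupported structure {type(structure).__name__}")

    records: list[CurvatureRecord] = []
    for k, e in enumerate(items, start=1):
        rec = CurvatureRecord(edge_id=_edge_label(structure, e))
        if "forman" in measures:
            rec.forman = _forman_dispatch(structure, e)
        if "daleth" in measures:
            rec.degree_difference = degree_difference(structure, e)
        if "ollivier" in measures:
            if isinstance(structure, DirectedGraph):
                res = _ollivier_dispatch(ollivier_target, digraph_edge_id(*e))
            else:
                res = _ollivier_dispatch(structure, e)
            rec.ollivier = res.value
            rec.m_vector = res.m_vector
        records.append(rec)
        if k % _PROGRESS_EVERY == 0:
            logger.info("computed %d/%d edges", k, len(items))
    return records


def _values(records: Iterable[CurvatureRecord], measure: str) -> list[float]:
    attr = {"forman": "forman", "daleth": "degree_difference", "ollivier": "ollivier"}[measure]
    return [float(getattr(r, attr)) for r in records if getattr(r, attr) is not None]


def summarize(
    records: Iterable[CurvatureRecord], measure: str, bin_width: Optional[float] = None
) -> SummaryReport:
    """Exact count/min/max/mean/median plus a fixed-width histogram anchored
    at the integer floor of the minimum."""
    if measure not in ALL_MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    values = _values(list(records), measure)
    if not values:
        raise ValueError(f"no values recorded for measure {measure!r}")
    width = float(bin_width) if bin_width is not None else DEFAULT_BIN_WIDTH[measure]
    if width <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = min(values), max(values)
    start = math.floor(lo)
    nbins = max(1, math.ceil((hi - start) / width + 1e-12))
    counts, _ = np.histogram(values, bins=nbins, range=(start, start + nbins * width))
    histogram = [
        (start + i * width, width, int(c)) for i, c in enumerate(counts)
    ]
    return SummaryReport(
        measure=measure,
        count=len(values),
        min=lo,
        max=hi,
        mean=statistics.fmean(values),
        median=float(statistics.median(values)),
        histogram=histogram,
    )


def degree_assortativity(G: UndirectedGraph) -> float:
    """Newman degree assortativity: Pearson correlation of degrees over the
    doubled edge list (shifting to excess degrees leaves the correlation
    unchanged).  Undefined — and rejected — for regular graphs."""
    g = G.to_networkx()
    if g.number_of_edges() < 2:
        raise ValueError("assortativity needs at least 2 edges")
    end_degrees = {g.degree(v) for e in g.edges for v in e}
    if len(end_degrees) < 2:
        raise ValueError("assortativity undefined for regular graphs")
    return float(nx.degree_assortativity_coefficient(g))


def giant_component(structure):
    """Largest connected component in the undirected sense (weak connectivity
    for digraphs; for hypergraphs, vertices are connected when they co-occur
    in a hyperedge)."""
    if isinstance(structure, UndirectedGraph):
        g = structure.to_networkx()
        if g.number_of_nodes() == 0:
            return UndirectedGraph()
        keep = max(nx.connected_components(g), key=len)
        out = UndirectedGraph(vertices=sorted(keep))
        for v, w in structure.edges:
            if v in keep:
                out.add_edge(v, w)
        return out
    if isinstance(structure, DirectedGraph):
        g = structure.to_networkx()
        if g.number_of_nodes() == 0:
            return DirectedGraph()
        keep = max(nx.weakly_connected_components(g), key=len)
        out = DirectedGraph(vertices=sorted(keep))
        for v, w in structure.edges:
            if v in keep:
                out.add_edge(v, w)
        return out
    if isinstance(structure, DirectedHypergraph):
        g = nx.Graph()
        g.add_nodes_from(structure.vertices)
        for e in structure.hyperedges:
            members = sorted(e.tail | e.head)
            g.add_edges_from(zip(members, members[1:]))
        if g.number_of_nodes() == 0:
            return DirectedHypergraph()
        keep = max(nx.connected_components(g), key=len)
        out = DirectedHypergraph(vertices=sorted(keep))
        for e in structure.hyperedges:
            if (e.tail | e.head) <= keep:
                out.add_hyperedge(e)
        return out
    raise TypeError(f"unsupported structure {type(structure).__name__}")
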