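"""Seeded synthetic generators and exact worked-example fixtures.

The fixtures encode the small constellations whose curvature values can be
checked by hand and anchor the whole test suite:

* ``fig3`` — the four-hyperedge metabolic toy whose red hyperedge
  e = ({src, t2}, {h2, snk}) has in-measure {src: 1/2, tm: 1/2}, out-measure
  {snk: 1/2, tm: 1/4, tr1: 1/8, tr2: 1/8}, transport cost 5/4 and Ollivier
  curvature -1/4.  The topology is reconstructed from the splitting
  walkthrough (source keeps 1/2; the sink hole is 1/2; mass and hole
  coincide at the top-middle vertex; the remaining 1/4 splits over the two
  top-right vertices) and validated by reproducing every one of those
  numbers.
* ``directed_path`` / ``directed_3cycle`` — the Ollivier extremes -2 and +1.
* ``isolated_hyperedge`` — O = 0, F = |e1| + |e2|.
* ``fig4_triangle`` / ``fig4_quadrangle`` / ``fig4_pentagon`` — a focal
  hyperedge plus one incoming and one outgoing hyperedge arranged so the
  mass-to-hole distance is 0, 1 or 2 (contributions to m0, m1, m2).

Generators are fully determined by their spec (same spec, same structure).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Union

from .model import (
    DirectedGraph,
    DirectedHyperedge,
    DirectedHypergraph,
    GraphError,
    UndirectedGraph,
)

__all__ = ["GeneratorSpec", "generate", "fixture", "FIXTURE_NAMES"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of a seeded random structure.

    kind: "er-graph" | "er-digraph" | "random-hypergraph";
    p: independent edge probability (ER kinds); m: hyperedge count;
    tail_size/head_size: inclusive integer ranges (hypergraph);
    allow_catalysts: permit tail/head overlap within one hyperedge.
    """

    kind: str
    n: int
    p: Optional[float] = None
    m: Optional[int] = None
    tail_size: tuple[int, int] = (1, 2)
    head_size: tuple[int, int] = (1, 2)
    seed: int = 0
    allow_catalysts: bool = False


def _labels(n: int) -> list[str]:
    return [f"v{i}" for i in range(n)]


def generate(spec: GeneratorSpec) -> Union[UndirectedGraph, DirectedGraph, DirectedHypergraph]:
    rng = random.Random(spec.seed)
    labels = _labels(spec.n)
    if spec.kind == "er-graph":
        if spec.p is None:
            raise ValueError("er-graph requires p")
        g = UndirectedGraph(vertices=labels)
        for i in range(spec.n):
            for j in range(i + 1, spec.n):
                if rng.random() < spec.p:
                    g.add_edge(labels[i], labels[j])
        return g
    if spec.kind == "er-digraph":
        if spec.p is None:
            raise ValueError("er-digraph requires p")
        d = DirectedGraph(vertices=labels)
        for i in range(spec.n):
            for j in range(spec.n):
                if i != j and rng.random() < spec.p:
                    d.add_edge(labels[i], labels[j])
        return d
    if spec.kind == "random-hypergraph":
        if spec.m is None:
            raise ValueError("random-hypergraph requires m")
        t_lo, t_hi = spec.tail_size
        h_lo, h_hi = spec.head_size
        if t_lo < 1 or h_lo < 1:
            raise ValueError("tail/head sizes must be >= 1")
        needed = t_hi + (0 if spec.allow_catalysts else h_hi)
        if t_hi > spec.n or h_hi > spec.n or needed > spec.n:
            raise ValueError(
                f"tail/head size ranges need up to {needed} distinct vertices, only {spec.n} exist"
            )
        H = DirectedHypergraph(vertices=labels)
        for k in range(spec.m):
            t = rng.randint(t_lo, t_hi)
            h = rng.randint(h_lo, h_hi)
            tail = rng.sample(labels, t)
            pool = labels if spec.allow_catalysts else [v for v in labels if v not in tail]
            head = rng.sample(pool, h)
            H.add_hyperedge(DirectedHyperedge(f"h{k}", frozenset(tail), frozenset(head)))
        return H
    raise ValueError(f"unknown generator kind {spec.kind!r}")


def _fig3() -> DirectedHypergraph:
    H = DirectedHypergraph(vertices=["src", "tm", "t2", "h2", "snk", "tr1", "tr2"])
    H.add_hyperedge(DirectedHyperedge("e", frozenset({"src", "t2"}), frozenset({"h2", "snk"})))
    H.add_hyperedge(DirectedHyperedge("f", frozenset({"tm"}), frozenset({"t2"})))
    H.add_hyperedge(DirectedHyperedge("g1", frozenset({"h2"}), frozenset({"tm"})))
    H.add_hyperedge(DirectedHyperedge("g2", frozenset({"h2"}), frozenset({"tr1", "tr2"})))
    return H


def _directed_path() -> DirectedGraph:
    return DirectedGraph(vertices=["u", "v", "w", "z"], edges=[("u", "v"), ("v", "w"), ("w", "z")])


def _directed_3cycle() -> DirectedGraph:
    return DirectedGraph(vertices=["u", "v", "w"], edges=[("u", "v"), ("v", "w"), ("w", "u")])


def _isolated_hyperedge() -> DirectedHypergraph:
    H = DirectedHypergraph(vertices=["a1", "a2", "b1", "b2", "b3"])
    H.add_hyperedge(DirectedHyperedge("e", frozenset({"a1", "a2"}), frozenset({"b1", "b2", "b3"})))
    return H


def _fig4(kind: str) -> DirectedHypergraph:
    # focal hyperedge e = ({a}, {b}) with one incoming (u -> a) and one
    # outgoing (b -> x or b -> u) hyperedge; extra hyperedges set the
    # mass-to-hole distance to 0 (triangle), 1 (quadrangle) or 2 (pentagon).
    if kind == "triangle":
        H = DirectedHypergraph(vertices=["u", "a", "b"])
        edges = [("e", {"a"}, {"b"}), ("f", {"u"}, {"a"}), ("g", {"b"}, {"u"})]
    elif kind == "quadrangle":
        H = DirectedHypergraph(vertices=["u", "a", "b", "x"])
        edges = [("e", {"a"}, {"b"}), ("f", {"u"}, {"a"}), ("g", {"b"}, {"x"}), ("s", {"u"}, {"x"})]
    elif kind == "pentagon":
        H = DirectedHypergraph(vertices=["u", "a", "b", "x", "y"])
        edges = [
            ("e", {"a"}, {"b"}),
            ("f", {"u"}, {"a"}),
            ("g", {"b"}, {"x"}),
            ("s1", {"u"}, {"y"}),
            ("s2", {"y"}, {"x"}),
        ]
    else:  # pragma: no cover
        raise ValueError(kind)
    for eid, tail, head in edges:
        H.add_hyperedge(DirectedHyperedge(eid, frozenset(tail), frozenset(head)))
    return H


_FIXTURES = {
    "fig3": _fig3,
    "directed_path": _directed_path,
    "directed_3cycle": _directed_3cycle,
    "isolated_hyperedge": _isolated_hyperedge,
    "fig4_triangle": lambda: _fig4("triangle"),
    "fig4_quadrangle": lambda: _fig4("quadrangle"),
    "fig4_pentagon": lambda: _fig4("pentagon"),
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def fixture(name: str) -> Union[UndirectedGraph, DirectedGraph, DirectedHypergraph]:
    """Return a named worked-example structure (fresh instance each call)."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}") from None
    return builder()
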