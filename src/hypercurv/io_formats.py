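"""Plain-text readers and writers: edge lists, hypergraph records, metabolic
reaction tables, and curvature result tables.

All formats are UTF-8, tab-delimited, with ``#`` comment lines.  A reaction
table row is ``id<TAB>direction<TAB>reactants<TAB>products`` with
comma-separated species; reversible reactions (direction ``rev``) are split
into a forward hyperedge ``id_f`` and a reverse hyperedge ``id_r`` with tail
and head swapped, so a model with R reactions of which r are reversible
yields (R - r) + 2r hyperedges.  Stoichiometric coefficients (a leading
integer on a species token, e.g. ``2 h``) are dropped: the hypergraph is
set-valued and unweighted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

from .forman import CurvatureRecord
from .model import (
    DirectedGraph,
    DirectedHyperedge,
    DirectedHypergraph,
    GraphError,
    UndirectedGraph,
)

__all__ = [
    "ParseError",
    "ReactionRecord",
    "read_edge_list",
    "read_hypergraph",
    "read_reaction_table",
    "write_edge_list",
    "write_hypergraph",
    "write_curvature_table",
    "read_curvature_table",
]

logger = logging.getLogger("hypercurv")

_COEFF = re.compile(r"^(\d+)\s+(\S.*)$")


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class ReactionRecord:
    """One parsed metabolic reaction (species sets deduplicated; a species on
    both sides — a catalyst — stays on both)."""

    id: str
    reversible: bool
    reactants: frozenset[str]
    products: frozenset[str]

    def __post_init__(self):
        if not self.reactants and not self.products:
            raise ParseError(f"reaction {self.id!r}: reactants and products both empty")


def _data_lines(path: Union[str, Path]):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_edge_list(path: Union[str, Path], directed: bool = False):
    """Two whitespace/tab-separated vertex labels per line.  Duplicate pairs
    collapse to one edge with a warning; self-loops are rejected with the
    offending line number."""
    graph = DirectedGraph() if directed else UndirectedGraph()
    seen: set[tuple[str, str]] = set()
    for lineno, line in _data_lines(path):
        parts = line.split("\t") if "\t" in line else line.split()
        parts = [p.strip() for p in parts if p.strip()]
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected two vertex labels, got {line!r}")
        a, b = parts
        if a == b:
            raise ParseError(f"{path}:{lineno}: self-loop {a!r} not allowed")
        key = (a, b) if directed else UndirectedGraph.canonical(a, b)
        if key in seen:
            logger.warning("%s:%d: duplicate edge %s collapsed", path, lineno, key)
            continue
        seen.add(key)
        graph.add_vertex(a)
        graph.add_vertex(b)
        graph.add_edge(a, b)
    return graph


def _split_vertex_list(cell: str, where: str) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    for token in cell.split(","):
        token = token.strip()
        if not token:
            continue
        if token in seen:
            logger.warning("%s: duplicate vertex %r deduplicated", where, token)
            continue
        seen.add(token)
        out.append(token)
    return out


def read_hypergraph(path: Union[str, Path]) -> DirectedHypergraph:
    """Lines ``id<TAB>t1,t2,...<TAB>h1,h2,...``; either vertex list may be
    empty, but not both."""
    H = DirectedHypergraph()
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
        eid = parts[0].strip()
        if not eid:
            raise ParseError(f"{path}:{lineno}: empty hyperedge id")
        tail = _split_vertex_list(parts[1], f"{path}:{lineno}")
        head = _split_vertex_list(parts[2], f"{path}:{lineno}")
        if not tail and not head:
            raise ParseError(f"{path}:{lineno}: tail and head cannot both be empty")
        if H.has_hyperedge(eid):
            raise ParseError(f"{path}:{lineno}: duplicate hyperedge id {eid!r}")
        for v in tail + head:
            H.add_vertex(v)
        H.add_hyperedge(DirectedHyperedge(eid, frozenset(tail), frozenset(head)))
    return H


def _parse_species(cell: str, where: str, state: dict) -> frozenset[str]:
    species: set[str] = set()
    for token in cell.split(","):
        token = token.strip()
        if not token:
            continue
        m = _COEFF.match(token)
        if m:
            if not state.get("coeff_warned"):
                logger.warning("%s: stoichiometric coefficients dropped (set-valued hypergraph)", where)
                state["coeff_warned"] = True
            token = m.group(2).strip()
        species.add(token)
    return frozenset(species)


def read_reaction_table(path: Union[str, Path]) -> DirectedHypergraph:
    """Metabolic reaction table -> directed hypergraph, splitting each
    reversible reaction into ``id_f`` (forward) and ``id_r`` (tail/head
    swapped)."""
    records = list(iter_reaction_records(path))
    H = DirectedHypergraph()
    for rec in records:
        for v in sorted(rec.reactants | rec.products):
            H.add_vertex(v)
        if rec.reversible:
            H.add_hyperedge(DirectedHyperedge(rec.id + "_f", rec.reactants, rec.products))
            H.add_hyperedge(DirectedHyperedge(rec.id + "_r", rec.products, rec.reactants))
        else:
            H.add_hyperedge(DirectedHyperedge(rec.id, rec.reactants, rec.products))
    return H


def iter_reaction_records(path: Union[str, Path]) -> Iterable[ReactionRecord]:
    state: dict = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 tab-separated columns, got {len(parts)}")
        rid, direction, reactants_cell, products_cell = (p.strip() for p in parts)
        if direction not in ("irrev", "rev"):
            raise ParseError(f"{path}:{lineno}: unknown direction token {direction!r}")
        where = f"{path}:{lineno}"
        reactants = _parse_species(reactants_cell, where, state)
        products = _parse_species(products_cell, where, state)
        if not reactants and not products:
            raise ParseError(f"{path}:{lineno}: reactants and products both empty")
        yield ReactionRecord(rid, direction == "rev", reactants, products)


def write_edge_list(path: Union[str, Path], graph) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in graph.edges:
            fh.write(f"{a}\t{b}\n")


def write_hypergraph(path: Union[str, Path], H: DirectedHypergraph) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in H.hyperedges:
            fh.write(f"{e.id}\t{','.join(sorted(e.tail))}\t{','.join(sorted(e.head))}\n")


_HEADER = ["edge_id", "forman", "degree_difference", "ollivier", "m0", "m1", "m2", "m3"]


def _fmt(x) -> str:
    if x is None:
        return "NA"
    f = float(x)
    if f == int(f) and abs(f) < 1e15:
        return str(int(f))
    return f"{f:.12g}"


def write_curvature_table(path: Union[str, Path], records: Iterable[CurvatureRecord]) -> None:
    """TSV with header edge_id, forman, degree_difference, ollivier, m0..m3;
    rationals rendered as decimals with 12 significant digits, absent fields
    as ``NA``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for rec in records:
            m = rec.m_vector if rec.m_vector is not None else (None,) * 4
            row = [rec.edge_id, _fmt(rec.forman), _fmt(rec.degree_difference), _fmt(rec.ollivier)]
            row += [_fmt(x) for x in m]
            fh.write("\t".join(row) + "\n")


def read_curvature_table(path: Union[str, Path]) -> list[CurvatureRecord]:
    records: list[CurvatureRecord] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HEADER:
            raise ParseError(f"{path}: unexpected header {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != len(_HEADER):
                raise ParseError(f"{path}:{lineno}: expected {len(_HEADER)} columns")

            def num(cell: str):
                return None if cell == "NA" else float(cell)

            m = tuple(num(c) for c in parts[4:8])
            fint = num(parts[1])
            dint = num(parts[2])
            records.append(
                CurvatureRecord(
                    edge_id=parts[0],
                    forman=None if fint is None else int(fint),
                    degree_difference=None if dint is None else int(dint),
                    ollivier=num(parts[3]),
                    m_vector=None if all(x is None for x in m) else m,
                )
            )
    return records
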