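"""Independent brute-force 1-Wasserstein solver for validating the main
transport code on small instances.

Rational marginals with common denominator D can be expanded into D unit
atoms of weight 1/D on each side; because the transportation polytope with
marginals on the 1/D grid has integral vertices after scaling by D, an
optimal transport plan can always be realised as a perfect matching of
atoms.  Minimising total distance over atom assignments is therefore an
exact, independent route to the transportation optimum: exhaustive
permutation search for D <= 8, exact min-cost assignment (Hungarian via
scipy) up to the guard D <= 64.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Mapping, Union

import numpy as np
from scipy.optimize import linear_sum_assignment

from .ollivier import VertexMeasure

__all__ = ["OracleError", "AtomExpansion", "expand_atoms", "brute_force_w1", "DENOMINATOR_GUARD"]

DENOMINATOR_GUARD = 64
EXHAUSTIVE_LIMIT = 8


class OracleError(ValueError):
    pass


@dataclass
class AtomExpansion:
    """Both measures expanded into D atoms of weight 1/D each."""

    atoms_a: list[str]
    atoms_b: list[str]
    denominator: int

    def __post_init__(self):
        assert len(self.atoms_a) == len(self.atoms_b) == self.denominator


def common_denominator(mu_a: VertexMeasure, mu_b: VertexMeasure) -> int:
    d = 1
    for mu in (mu_a, mu_b):
        for w in mu.entries.values():
            d = math.lcm(d, w.denominator)
    return d


def expand_atoms(mu_a: VertexMeasure, mu_b: VertexMeasure) -> AtomExpansion:
    D = common_denominator(mu_a, mu_b)

    def expand(mu: VertexMeasure) -> list[str]:
        atoms: list[str] = []
        for v in mu.support:
            count = mu[v] * D
            assert count.denominator == 1
            atoms.extend([v] * int(count))
        return atoms

    return AtomExpansion(expand(mu_a), expand(mu_b), D)


def brute_force_w1(
    mu_a: VertexMeasure,
    mu_b: VertexMeasure,
    dist: Union[Mapping[tuple[str, str], int], Callable[[str, str], int]],
    guard: int = DENOMINATOR_GUARD,
) -> Fraction:
    """Exact W1 by optimal atom assignment.  Raises beyond the guard
    denominator; large instances belong to the LP path of
    :func:`hypercurv.ollivier.wasserstein1`."""
    expansion = expand_atoms(mu_a, mu_b)
    D = expansion.denominator
    if D > guard:
        raise OracleError(
            f"common denominator {D} exceeds the oracle guard {guard}; use the LP path"
        )
    lookup = dist if callable(dist) else lambda u, v: dist[(u, v)]
    cost = [[lookup(u, v) for v in expansion.atoms_b] for u in expansion.atoms_a]

    if D <= EXHAUSTIVE_LIMIT:
        best = min(
            sum(cost[i][perm[i]] for i in range(D))
            for perm in itertools.permutations(range(D))
        )
    else:
        rows, cols = linear_sum_assignment(np.asarray(cost))
        best = int(sum(cost[i][j] for i, j in zip(rows, cols)))
    return Fraction(best, D)
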