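# Methods

## Scope and model

`hypercurv` computes three edge-based geometric measures on three classes of
unweighted structure — undirected graphs, directed graphs, and directed
hypergraphs — with the directed hypergraph as the central object. A
hyperedge is an ordered pair of vertex subsets `(e1, e2)` ("tail" and
"head"), the natural model of a chemical reaction (reactants → products); a
directed graph edge is the special case of singleton tail and head, and the
package makes that embedding explicit (`digraph_to_hypergraph`) so directed
graphs and hypergraphs share one transport code path, verified edge-for-edge
in the tests.

### Forman–Ricci curvature

For an undirected edge, `F(e) = 2 − deg(e)`, where `deg(e)` is the number of
edges sharing a vertex with `e` (an edge is not its own neighbour);
equivalently `2 − (deg(v)−1) − (deg(w)−1)`. Both forms are computed by
independent routes and compared in the tests. For a directed edge
`e = (v, w)`, `F(e) = 2 − deg_in(e) − deg_out(e)` with `deg_in` the number
of edges whose head is `v` and `deg_out` those whose tail is `w`; the
definition is purely incidence-based, so an antiparallel edge `(w, v)`
contributes to both counts. For a hyperedge,
`F(e) = |e1| + |e2| − deg_in(e) − deg_out(e)` with **multiplicity
counting**: an incoming hyperedge is counted once per tail vertex of `e` in
its head (symmetrically for outgoing). A catalyst vertex (present in both
tail and head) contributes to both `|e1|` and `|e2|` and both degree sums.
The focal hyperedge is always excluded from its own incoming/outgoing lists,
even when tail and head overlap; curvature of genuine directed hyperloops is
out of scope.

### Degree difference

`daleth(e) = |deg_v(e) − deg_w(e)|` for undirected edges (non-negative,
invariant under endpoint order), and the signed `deg_out(e) − deg_in(e)` for
directed edges and hyperedges, using the same counting conventions as the
Forman variant. Positive values mark "productive" relations, negative
"receptive" ones; the distribution is a local assortativity profile.

### Ollivier–Ricci curvature

`O(e) = 1 − W1(μ_in, μ_out)`, the 1-Wasserstein distance between the
probability measures on the two sides of the edge, with the equivalent
decomposition `O(e) = m0 − m2 − 2·m3` where `m_i` is the mass an optimal
plan moves at ground distance `i`. Both identities are asserted exactly for
every computed edge. The value is bounded in `[−2, 1]`: mass never travels
farther than 3 because the route through `e` itself (mass → tail, tail →
head via `e`, head → hole) always exists.

**Measure construction (hypergraphs).** Each of the `η_in` tail vertices
starts with `1/η_in`. A *source* (tail vertex with no other incoming
hyperedge) keeps its share in place; otherwise the share is split evenly
over the incoming hyperedges at that vertex, and each hyperedge's portion
evenly over its tail vertices (the *masses*, set ℳ). The out-measure
mirrors this on the head side (*sinks* and *holes*, set ℋ). All weights are
exact `fractions.Fraction`s; contributions to the same vertex accumulate.
Following the set definition, ℳ/ℋ as reported by `mass_set`/`hole_set`
exclude sources/sinks, which are visible in the measure support instead.

**Measures are vertex-indexed.** The classical directed-graph formulation
attaches weights to incoming/outgoing *edges* and measures distance from the
tail of one to the head of the other; mapping each edge's weight to that
tail (resp. head) vertex gives the identical transport problem and unifies
graphs with hypergraphs. For an undirected edge `(v, w)`, `μ_v` is uniform
over the far endpoints of the edges at `v` — including `w`, since the edge
set at `v` contains `e` itself — and the ground distance is the unrestricted
shortest-path distance in the graph (it may traverse `e`).

**Degenerate sides.** A hyperedge may structurally have one empty side
(e.g. an exchange reaction); curvature is undefined there and the measure
constructor raises rather than guessing. An *incoming* hyperedge with an
empty tail cannot carry mass, so it is excluded from the recipient count,
and a tail vertex fed only by tail-less hyperedges is treated as a source
(mirror rule on the head side).

## Optimal transport: solvers and numerics

* **Exact path** (default up to 1024 cost-matrix cells): a transportation
  simplex over exact rationals — northwest-corner start, tree duals,
  Bland-style pivoting (lexicographically first entering cell with negative
  reduced cost, lexicographically smallest leaving minimiser), which
  precludes cycling under degeneracy. Costs, plans and curvatures are exact
  `Fraction`s; every acceptance identity is asserted with `==`.
* **LP path** (larger instances, e.g. genome-scale metabolic reactions with
  hundreds of masses and holes): the same transportation problem as a
  sparse `scipy.optimize.linprog` (HiGHS) program over floats. Cross-checked
  against the exact path to 1e−9 in the tests; table output renders 12
  significant digits.
* **Independent oracle** (`hypercurv.oracle`, test-only): both measures are
  expanded into `D` atoms of weight `1/D` (`D` = lcm of the weight
  denominators, guarded at `D ≤ 64`); because the scaled transportation
  polytope is integral, an optimal plan is realisable as a perfect matching
  of atoms, found by exhaustive permutation search (`D ≤ 8`) or exact
  Hungarian assignment. The oracle shares no code with the simplex or the
  LP and agrees exactly on every guarded instance of the seeded random
  suite (hundreds of edges across graphs, digraphs and hypergraphs).

Optimal plans are generally non-unique (the worked example has two optimal
m-vectors); the solver returns one optimal plan, and only the cost — hence
`O(e)` — is canonical. `m0` is canonical in the worked example and asserted.
Ground distances are computed by BFS truncated at depth 3 (hyperpath steps
go from any tail vertex of a hyperedge to any of its head vertices); a
mass–hole pair farther than 3 apart is impossible by construction and
treated as a data-corruption error.

## Synthetic generators and fixtures

`synth.generate` produces Erdős–Rényi graphs/digraphs (independent edge
probability `p`) and random hypergraphs (`m` hyperedges, tail/head sizes
uniform on given ranges, membership sampled without replacement), fully
determined by the spec's seed. Defaults used throughout the test suite:
`n = 8` vertices, `p = 0.35`, `m = 7` hyperedges with side sizes 1–3 —
small enough that the exact solver, the LP and the oracle can all be run on
every edge, dense enough that sources, sinks, coincidences and detours all
occur. Tail/head overlap (catalysts) is off by default so that random tests
avoid the hyperloop ambiguity; an `allow_catalysts` flag enables it.

`synth.fixture` returns the hand-checkable constellations: the
four-hyperedge worked example (`fig3`, reconstructed from the splitting
walkthrough and validated by reproducing every printed weight, the cost 5/4,
the curvature −1/4 and both optimal m-vectors), the directed path and
3-cycle (the extremes −2 and 1), the isolated hyperedge (`O = 0`,
`F = |e1|+|e2|`), and three motif fixtures placing the single mass at
distance 0/1/2 from the single hole (contributions to `m0`/`m1`/`m2`).

What the generators do **not** emulate: degree heterogeneity (hubs,
scale-free tails), modularity, currency metabolites shared by half the
reactions, or biological component structure. Passing tests therefore
demonstrate correctness of the measures, not that real networks have any
particular curvature distribution.

## Statistics layer

`summarize` reports count/min/max/mean/median and a fixed-width histogram
anchored at `floor(min)` (default widths 1 for the integer measures, 0.05
for Ollivier); bins are contiguous and partition the values.
`degree_assortativity` uses the standard Newman estimator via
`networkx.degree_assortativity_coefficient` (Pearson correlation of degrees
over the doubled edge list; shifting to excess degrees leaves a correlation
unchanged) and rejects regular graphs, where it is undefined. Giant-component
extraction is undirected-sense (weak connectivity for digraphs; for
hypergraphs, vertices are connected when they co-occur in a hyperedge).

## Metabolic pipeline and problem sizes

`read_reaction_table` converts a reaction table to a hypergraph: each
reversible reaction splits into `id_f` and `id_r` (tail/head swapped), so
the hyperedge count is `#irreversible + 2·#reversible`; stoichiometric
coefficients are dropped (the hypergraph is set-valued and unweighted) with
one warning per file; species appearing on both sides are retained on both.
No currency-metabolite filtering is applied by default. Genome-scale
reproduction (e.g. the *M. tuberculosis* iNJ661 model: 1195 hyperedges, the
ATP-forming reaction at `F = −1347`, `daleth = 1`, `|ℳ| = 400`,
`O = 0.35`) requires the externally converted table — see
`docs/bigg_conversion.md`; the corresponding integration test runs whenever
`data/iNJ661_reactions.tsv` is present. The always-run test suite exercises
the same pipeline on synthetic tables; the randomized identity suite uses
200 structures at `n ≤ 8` so that all three transport routes run on every
edge in seconds.

## Known limitations

* Weighted structures, augmented Forman curvature with inserted 2-faces,
  vertex-flow curvature, idleness/lazy-walk Ollivier variants and curvature
  flow are out of scope.
* Hyperedges with an empty tail or head are structurally accepted but have
  no curvature.
* The m-vector of a returned plan is solver-dependent wherever the optimum
  is non-unique; only cost and curvature are canonical.
* SBML/BiGG parsing is deliberately not implemented; the reaction-table
  format is the interchange point.
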