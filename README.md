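# hypercurv

Edge-based curvature analysis for biological networks: **Forman–Ricci
curvature**, **degree difference** and **Ollivier–Ricci curvature** on
undirected graphs (protein–protein interaction networks), directed graphs
(transcriptional regulatory networks) and directed hypergraphs (metabolic
reaction networks), with exact rational optimal transport.

Network analysis usually attaches numbers to vertices; curvature measures
instead quantify the *relations* — how, and how well, each (hyper)edge is
connected to the others. For an edge `e`:

* `F(e) = 2 − deg(e)` (graphs) or `F(e) = |e1| + |e2| − deg_in(e) − deg_out(e)`
  (directed hyperedges `e1 → e2`, with incoming hyperedges counted once per
  tail vertex they feed): very negative on edges joining hubs.
* `ℸ(e) = |deg_v − deg_w|` (undirected) or the signed `deg_out − deg_in`
  (directed): a local (dis)assortativity indicator.
* `O(e) = 1 − W1(μ_in, μ_out) = m0 − m2 − 2·m3 ∈ [−2, 1]`, where `W1` is the
  1-Wasserstein cost of transporting the measure describing what feeds `e`
  onto the measure describing what it feeds, and `m_i` is the mass moved at
  distance `i` in an optimal plan. Directed triangles (`m0`) push it up;
  mass forced through `e` itself (`m3`) pushes it toward −2.

For hyperedges the two measures are built by an even-splitting cascade over
sources and "masses" (tail side) and sinks and "holes" (head side), in exact
rational arithmetic; transport plans come from an exact transportation
simplex (small instances) or a HiGHS LP (genome-scale reactions), with an
independent brute-force assignment oracle validating both in the tests.

## Worked example

The four-hyperedge constellation around a "red" hyperedge
`e = ({src, t2}, {h2, snk})`, fed by `f = ({tm}, {t2})` and drained by
`g1 = ({h2}, {tm})` and `g2 = ({h2}, {tr1, tr2})`:

```python
>>> from hypercurv import fixture, hyper_in_measure, hyper_out_measure, ollivier
>>> H = fixture("fig3")
>>> hyper_in_measure(H, "e").entries
{'src': Fraction(1, 2), 'tm': Fraction(1, 2)}
>>> hyper_out_measure(H, "e").entries
{'tm': Fraction(1, 4), 'tr1': Fraction(1, 8), 'tr2': Fraction(1, 8), 'snk': Fraction(1, 2)}
>>> res = ollivier(H, "e")
>>> res.value, res.plan.cost, res.m_vector
(Fraction(-1, 4), Fraction(5, 4), (Fraction(1, 4), Fraction(1, 2), Fraction(0, 1), Fraction(1, 4)))
```

`src` is a source and keeps its ½; the other ½ flows back to `tm`. On the
out side the sink holds ½, `tm` ¼, and the last ¼ splits over `tr1`/`tr2`.
A quarter of the mass is already in place (`m0 = 1/4`), half moves distance
1, and the final quarter must travel distance 3 through `e` — total cost
5/4, curvature `O(e) = 1 − 5/4 = −1/4`: mildly negatively curved.

The scripts in `examples/` walk through this example, a miniature metabolic
model (reversible-reaction splitting, catalysts, mass/hole sets) and a
random-graph distribution summary.

## Command line

```
curv synth --kind fig3 --output fig3.tsv
curv compute --input fig3.tsv --type hypergraph --output curv.tsv
curv summarize --input curv.tsv --measure ollivier
```

`curv compute` accepts `--type undirected|directed|hypergraph|reactions`
(the latter reads a metabolic reaction table and splits reversible
reactions), a `--measures` subset to skip the expensive transport step, and
`--giant` to restrict to the giant component. Converting a BiGG/SBML model
to the reaction-table format is a five-line `cobrapy` script — see
`docs/bigg_conversion.md`.

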