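"""Optimal-transport curvature: measures, distances, W1, O(e)."""

from __future__ import annotations

from collections import defaultdict
from fractions import Fraction as F

import pytest

from hypercurv import (
    DirectedGraph,
    DirectedHyperedge,
    DirectedHypergraph,
    MeasureError,
    UndirectedGraph,
    VertexMeasure,
    digraph_to_hypergraph,
    fixture,
    hole_set,
    hyper_distance,
    hyper_in_measure,
    hyper_out_measure,
    mass_set,
    ollivier,
    undirected_measures,
    wasserstein1,
)
from hypercurv.model import digraph_edge_id
from hypercurv.synth import GeneratorSpec, generate


def plan_marginals(plan):
    row, col = defaultdict(F), defaultdict(F)
    for (u, v), q in plan.moves.items():
        row[u] += q
        col[v] += q
    return dict(row), dict(col)


class TestUndirectedMeasures:
    def test_isolated_edge_point_masses(self):
        g = UndirectedGraph(vertices=["v", "w"], edges=[("v", "w")])
        mu_v, mu_w = undirected_measures(g, ("v", "w"))
        assert mu_v.entries == {"w": F(1)}
        assert mu_w.entries == {"v": F(1)}

    def test_triangle_uniform_on_neighbours(self, k3):
        mu_a, _ = undirected_measures(k3, ("a", "b"))
        assert mu_a.entries == {"b": F(1, 2), "c": F(1, 2)}

    def test_path_measure_includes_far_endpoint(self, p4):
        mu_b, _ = undirected_measures(p4, ("b", "c"))
        assert mu_b.entries == {"a": F(1, 2), "c": F(1, 2)}


class TestHyperMeasures:
    def test_fig3_in_measure(self, fig3):
        assert hyper_in_measure(fig3, "e").entries == {"src": F(1, 2), "tm": F(1, 2)}

    def test_fig3_out_measure(self, fig3):
        assert hyper_out_measure(fig3, "e").entries == {
            "snk": F(1, 2),
            "tm": F(1, 4),
            "tr1": F(1, 8),
            "tr2": F(1, 8),
        }

    def test_isolated_hyperedge_uniform_on_sources(self):
        H = fixture("isolated_hyperedge")
        assert hyper_in_measure(H, "e").entries == {"a1": F(1, 2), "a2": F(1, 2)}
        assert hyper_out_measure(H, "e").entries == {"b1": F(1, 3), "b2": F(1, 3), "b3": F(1, 3)}

    def test_head_only_hyperedge_rejected(self):
        H = DirectedHypergraph(vertices=["a"])
        H.add_hyperedge(DirectedHyperedge("e", frozenset(), frozenset({"a"})))
        with pytest.raises(MeasureError, match="head-only"):
            hyper_in_measure(H, "e")

    def test_fig3_mass_and_hole_sets_exclude_sources_and_sinks(self, fig3):
        assert mass_set(fig3, "e") == {"tm"}
        assert hole_set(fig3, "e") == {"tm", "tr1", "tr2"}

    def test_measures_are_exact_probability_distributions(self):
        for seed in range(30):
            H = generate(
                GeneratorSpec(
                    kind="random-hypergraph", n=8, m=7, tail_size=(1, 3), head_size=(1, 3), seed=seed
                )
            )
            for e in H.hyperedges:
                for mu in (hyper_in_measure(H, e.id), hyper_out_measure(H, e.id)):
                    assert sum(mu.entries.values()) == 1
                    assert all(w > 0 for w in mu.entries.values())

    def test_tailless_incoming_hyperedge_cannot_carry_mass(self):
        # t's only incoming hyperedge has an empty tail: t acts as a source
        H = DirectedHypergraph(vertices=["t", "b"])
        H.add_hyperedge(DirectedHyperedge("e", frozenset({"t"}), frozenset({"b"})))
        H.add_hyperedge(DirectedHyperedge("xch", frozenset(), frozenset({"t"})))
        assert hyper_in_measure(H, "e").entries == {"t": F(1)}


class TestHyperDistance:
    @pytest.mark.parametrize(
        "u,v,expected",
        [("tm", "tm", 0), ("src", "snk", 1), ("tm", "tr1", 3), ("src", "tm", 2)],
    )
    def test_fig3_distances(self, fig3, u, v, expected):
        assert hyper_distance(fig3, u, v) == expected

    def test_unreachable_within_three_returns_none(self, fig3):
        assert hyper_distance(fig3, "snk", "src") is None


class TestWasserstein:
    def test_identical_measures_cost_zero(self):
        mu = VertexMeasure({"a": F(1, 2), "b": F(1, 2)})
        dist = {(u, v): (0 if u == v else 1) for u in "ab" for v in "ab"}
        plan = wasserstein1(mu, mu, dist)
        assert plan.cost == 0 and plan.m_vector[0] == 1

    def test_point_masses_at_distance_three(self):
        plan = wasserstein1(
            VertexMeasure({"u": F(1)}), VertexMeasure({"v": F(1)}), {("u", "v"): 3}
        )
        assert plan.cost == 3 and plan.m_vector == (0, 0, 0, 1)

    def test_fig3_cost_and_plan(self, fig3):
        mu_in, mu_out = hyper_in_measure(fig3, "e"), hyper_out_measure(fig3, "e")
        dist = {
            (u, v): hyper_distance(fig3, u, v) for u in mu_in.support for v in mu_out.support
        }
        plan = wasserstein1(mu_in, mu_out, dist)
        assert plan.cost == F(5, 4)
        rows, cols = plan_marginals(plan)
        assert rows == mu_in.entries and cols == mu_out.entries

    def test_lp_route_matches_exact_route(self, fig3):
        mu_in, mu_out = hyper_in_measure(fig3, "e"), hyper_out_measure(fig3, "e")
        dist = {
            (u, v): hyper_distance(fig3, u, v) for u in mu_in.support for v in mu_out.support
        }
        exact = wasserstein1(mu_in, mu_out, dist, method="exact")
        lp = wasserstein1(mu_in, mu_out, dist, method="lp")
        assert abs(lp.cost - float(exact.cost)) < 1e-9
        assert sum(lp.m_vector) == pytest.approx(1.0, abs=1e-9)


class TestOllivier:
    def test_fig3_value_and_plan(self, fig3):
        res = ollivier(fig3, "e")
        assert res.value == F(-1, 4)
        assert res.plan.cost == F(5, 4)
        assert res.m_vector in {
            (F(1, 4), F(1, 2), F(0), F(1, 4)),
            (F(1, 4), F(1, 4), F(1, 2), F(0)),
        }

    def test_directed_path_attains_lower_extreme(self):
        assert ollivier(fixture("directed_path"), ("v", "w")).value == -2

    def test_directed_3cycle_attains_upper_extreme(self):
        res = ollivier(fixture("directed_3cycle"), ("v", "w"))
        assert res.value == 1 and res.m_vector[0] == 1

    def test_isolated_hyperedge_is_flat(self):
        assert ollivier(fixture("isolated_hyperedge"), "e").value == 0

    def test_k3_undirected(self, k3):
        assert ollivier(k3, ("a", "b")).value == F(1, 2)

    def test_vertex_transitive_symmetry(self):
        # C5: every edge equivalent, so O identical across edges
        cycle = UndirectedGraph(
            vertices=[f"v{i}" for i in range(5)],
            edges=[(f"v{i}", f"v{(i + 1) % 5}") for i in range(5)],
        )
        values = {ollivier(cycle, e).value for e in cycle.edges}
        assert len(values) == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_directed_graph_equals_hypergraph_embedding(self, seed):
        d = generate(GeneratorSpec(kind="er-digraph", n=8, p=0.3, seed=seed))
        H = digraph_to_hypergraph(d)
        for v, w in d.edges:
            res_d = ollivier(d, (v, w))
            res_h = ollivier(H, digraph_edge_id(v, w))
            assert res_d.value == res_h.value
            assert res_d.m_vector == res_h.m_vector

    def test_identities_and_bounds_on_random_structures(self):
        for seed in range(12):
            kind = ("er-graph", "er-digraph", "random-hypergraph")[seed % 3]
            s = generate(
                GeneratorSpec(kind=kind, n=8, p=0.4, m=7, tail_size=(1, 3), head_size=(1, 3), seed=seed)
            )
            edges = [e.id for e in s.hyperedges] if isinstance(s, DirectedHypergraph) else s.edges
            for e in edges:
                res = ollivier(s, e)
                m0, m1, m2, m3 = res.m_vector
                assert m0 + m1 + m2 + m3 == 1
                assert res.value == 1 - res.plan.cost == m0 - m2 - 2 * m3
                assert F(-2) <= res.value <= 1
                rows, cols = plan_marginals(res.plan)
                assert rows == res.mu_in.entries and cols == res.mu_out.entries
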