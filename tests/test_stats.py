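"""Batch driver, distribution summaries, assortativity, and the curv CLI."""

from __future__ import annotations

import json

import pytest
from click.testing import CliRunner

from hypercurv import (
    UndirectedGraph,
    compute_all,
    degree_assortativity,
    fixture,
    giant_component,
    summarize,
)
from hypercurv.cli import cli, main
from hypercurv.io_formats import read_curvature_table, write_edge_list, write_hypergraph


class TestComputeAll:
    def test_p4_forman_in_path_order(self, p4):
        recs = compute_all(p4, measures={"forman"})
        assert [r.forman for r in recs] == [1, 0, 1]
        assert all(r.ollivier is None for r in recs)

    def test_fig3_full_records(self, fig3):
        recs = compute_all(fig3)
        by_id = {r.edge_id: r for r in recs}
        assert set(by_id) == {"e", "f", "g1", "g2"}
        assert by_id["e"].forman == 1
        assert float(by_id["e"].ollivier) == -0.25

    def test_empty_structure(self):
        assert compute_all(UndirectedGraph()) == []

    def test_deterministic_and_order_stable(self, fig3):
        a = compute_all(fig3)
        b = compute_all(fig3)
        assert [r.edge_id for r in a] == [r.edge_id for r in b] == ["e", "f", "g1", "g2"]
        assert [(r.forman, r.ollivier) for r in a] == [(r.forman, r.ollivier) for r in b]

    def test_unknown_measure_rejected(self, p4):
        with pytest.raises(ValueError, match="unknown measures"):
            compute_all(p4, measures={"betweenness"})


class TestSummarize:
    def test_mean_min_max(self, p4):
        recs = compute_all(p4, measures={"forman"})
        rep = summarize(recs, "forman")
        assert rep.count == 3
        assert rep.min == 0 and rep.max == 1
        assert rep.mean == pytest.approx(2 / 3)

    def test_single_value_single_bin(self, k3):
        recs = compute_all(k3, measures={"ollivier"})
        rep = summarize(recs, "ollivier", bin_width=0.05)
        assert rep.count == 3
        assert sum(c for _, _, c in rep.histogram) == 3
        assert rep.median == 0.5

    def test_histogram_partitions_counts(self):
        g = fixture("directed_path")
        recs = compute_all(g, measures={"forman", "daleth"})
        for measure in ("forman", "daleth"):
            rep = summarize(recs, measure)
            assert sum(c for _, _, c in rep.histogram) == rep.count
            # contiguous bins
            for (lo1, w, _), (lo2, _, _) in zip(rep.histogram, rep.histogram[1:]):
                assert lo2 == pytest.approx(lo1 + w)

    def test_all_equal_median(self, k3):
        recs = compute_all(k3, measures={"forman"})
        rep = summarize(recs, "forman")
        assert rep.median == rep.min == rep.max == 0.0

    def test_no_values_rejected(self, p4):
        recs = compute_all(p4, measures={"forman"})
        with pytest.raises(ValueError, match="no values"):
            summarize(recs, "ollivier")


class TestAssortativity:
    def test_star_is_perfectly_disassortative(self, star_k14):
        assert degree_assortativity(star_k14) == pytest.approx(-1.0)

    def test_regular_graph_rejected(self):
        c4 = UndirectedGraph(
            vertices=["a", "b", "c", "d"],
            edges=[("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")],
        )
        with pytest.raises(ValueError, match="regular"):
            degree_assortativity(c4)

    def test_disjoint_regular_union_rejected(self):
        g = UndirectedGraph(vertices=["a", "b", "c", "d"], edges=[("a", "b"), ("c", "d")])
        with pytest.raises(ValueError, match="regular"):
            degree_assortativity(g)


class TestGiantComponent:
    def test_keeps_largest_undirected_component(self):
        g = UndirectedGraph(
            vertices=["a", "b", "c", "x", "y"],
            edges=[("a", "b"), ("b", "c"), ("x", "y")],
        )
        giant = giant_component(g)
        assert giant.vertices == {"a", "b", "c"}
        assert len(giant.edges) == 2

    def test_hypergraph_components_via_shared_vertices(self, fig3):
        fig3.add_vertex("lone")
        giant = giant_component(fig3)
        assert "lone" not in giant.vertices
        assert len(giant.hyperedges) == 4


class TestCli:
    def test_compute_then_summarize(self, tmp_path, fig3):
        inp = tmp_path / "fig3.tsv"
        out = tmp_path / "curv.tsv"
        write_hypergraph(inp, fig3)
        runner = CliRunner()
        res = runner.invoke(
            cli,
            ["compute", "--input", str(inp), "--type", "hypergraph", "--output", str(out)],
        )
        assert res.exit_code == 0, res.output
        records = read_curvature_table(out)
        assert {r.edge_id for r in records} == {"e", "f", "g1", "g2"}

        res = runner.invoke(cli, ["summarize", "--input", str(out), "--measure", "ollivier"])
        assert res.exit_code == 0, res.output
        report = json.loads(res.output)
        assert report["count"] == 4
        assert report["measure"] == "ollivier"

    def test_synth_writes_fixture(self, tmp_path):
        out = tmp_path / "fig3.tsv"
        runner = CliRunner()
        res = runner.invoke(cli, ["synth", "--kind", "fig3", "--output", str(out)])
        assert res.exit_code == 0, res.output
        assert len(out.read_text().strip().splitlines()) == 4

    def test_exit_code_usage_error(self):
        assert main(["compute", "--type", "undirected"]) == 1

    def test_exit_code_data_error(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("a\ta\n")
        code = main(
            ["compute", "--input", str(bad), "--type", "undirected", "--output", str(tmp_path / "o")]
        )
        assert code == 2

    def test_giant_flag(self, tmp_path):
        g = UndirectedGraph(
            vertices=["a", "b", "c", "x", "y"],
            edges=[("a", "b"), ("b", "c"), ("x", "y")],
        )
        inp = tmp_path / "g.tsv"
        out = tmp_path / "c.tsv"
        write_edge_list(inp, g)
        runner = CliRunner()
        res = runner.invoke(
            cli,
            [
                "compute",
                "--input", str(inp),
                "--type", "undirected",
                "--measures", "forman",
                "--giant",
                "--output", str(out),
            ],
        )
        assert res.exit_code == 0, res.output
        assert len(read_curvature_table(out)) == 2
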