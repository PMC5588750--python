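"""Enrichment arithmetic, BH adjustment, KGML parsing, coordinated runs."""

from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from gutmtx import pathways as pw


class TestHypergeom:
    def test_set_equals_universe_p_one(self):
        universe = {f"u{i}" for i in range(10)}
        res = pw.hypergeom_enrich({"all": set(universe)}, universe, {"u1", "u2"})
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_exact_tail_value(self):
        # N=20, K=5, n=8, k=4 -> 7280/125970
        universe = {f"u{i}" for i in range(20)}
        members = {f"u{i}" for i in range(5)}
        draws = {f"u{i}" for i in range(4)} | {f"u{i}" for i in range(10, 14)}
        res = pw.hypergeom_enrich({"s": members}, universe, draws)
        assert res["k"].iloc[0] == 4
        assert res["p"].iloc[0] == pytest.approx(7280 / 125970, rel=1e-12)

    def test_small_sets_excluded(self):
        universe = {"a", "b", "c"}
        res = pw.hypergeom_enrich({"tiny": {"a"}, "ok": {"a", "b"}}, universe, {"a"})
        assert list(res["set_id"]) == ["ok"]

    def test_empty_draws_all_p_one(self):
        universe = {"a", "b", "c", "d"}
        res = pw.hypergeom_enrich({"s": {"a", "b"}}, universe, set())
        assert (res["p"] == 1.0).all()

    def test_universe_growth_outside_sets_sharpens_enrichment(self):
        """Diluting the universe with units outside every set makes the same
        overlap more surprising: p never increases."""
        members = {f"m{i}" for i in range(4)}
        draws = {"m0", "m1", "x0"}
        universe = members | {"x0", "x1", "x2"}
        p_small = pw.hypergeom_enrich({"s": members}, universe, draws)["p"].iloc[0]
        p_big = pw.hypergeom_enrich({"s": members}, universe | {"y"}, draws)["p"].iloc[0]
        assert p_big <= p_small + 1e-15


class TestBh:
    def test_single_p(self):
        assert pw.bh_adjust([0.2]).tolist() == [0.2]

    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(
            pw.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_bounds_and_order(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        q = pw.bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        # order preserved: smaller p never gets larger q
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestKgml:
    def _chain_kgml(self, tmp_path, middle_reversible=False):
        mid = "reversible" if middle_reversible else "irreversible"
        text = f"""<?xml version="1.0"?>
<pathway name="path:toy00001" org="toy" number="00001" title="toy chain">
  <entry id="1" name="ec:1.1.1.1" type="enzyme" reaction="rn:R1"/>
  <entry id="2" name="ec:2.2.2.2" type="enzyme" reaction="rn:R2"/>
  <entry id="3" name="ec:3.3.3.3" type="enzyme" reaction="rn:R3"/>
  <entry id="4" name="ec:4.4.4.4" type="enzyme"/>
  <reaction id="1" name="rn:R1" type="irreversible">
    <substrate id="c1" name="cpd:C1"/><product id="c2" name="cpd:C2"/>
  </reaction>
  <reaction id="2" name="rn:R2" type="{mid}">
    <substrate id="c2" name="cpd:C2"/><product id="c3" name="cpd:C3"/>
  </reaction>
  <reaction id="3" name="rn:R3" type="irreversible">
    <substrate id="c3" name="cpd:C3"/><product id="c4" name="cpd:C4"/>
  </reaction>
</pathway>"""
        path = tmp_path / "toy.kgml"
        path.write_text(text)
        return path

    def test_chain_graph(self, tmp_path):
        g = pw.build_pathway_graph(self._chain_kgml(tmp_path))
        assert set(g.edges) == {("1.1.1.1", "2.2.2.2"), ("2.2.2.2", "3.3.3.3")}

    def test_reversible_adds_back_edges(self, tmp_path):
        g = pw.build_pathway_graph(self._chain_kgml(tmp_path, middle_reversible=True))
        assert ("2.2.2.2", "1.1.1.1") in g.edges

    def test_isolated_declared_enzyme_present(self, tmp_path):
        g = pw.build_pathway_graph(self._chain_kgml(tmp_path))
        assert "4.4.4.4" in g.nodes and g.degree("4.4.4.4") == 0

    def test_malformed_xml_raises(self, tmp_path):
        bad = tmp_path / "bad.kgml"
        bad.write_text("<pathway><entry></pathway>")
        with pytest.raises(ValueError, match="malformed"):
            pw.build_pathway_graph(bad)

    def test_no_ec_annotations_raises(self, tmp_path):
        bad = tmp_path / "noec.kgml"
        bad.write_text(
            '<pathway name="p"><entry id="1" name="gene:x" type="gene"/></pathway>'
        )
        with pytest.raises(ValueError, match="edge-list"):
            pw.build_pathway_graph(bad)

    def test_edge_list_roundtrip(self, tmp_path):
        g = nx.DiGraph()
        g.add_edges_from([("1.1.1.1", "2.2.2.2")])
        g.add_node("9.9.9.9")
        pw.write_edge_list(g, tmp_path / "p.tsv")
        back = pw.build_pathway_graph(tmp_path / "p.tsv")
        assert sorted(back.edges) == sorted(g.edges)
        assert sorted(back.nodes) == sorted(g.nodes)


class TestRuns:
    def _chain(self, ecs):
        g = nx.DiGraph()
        g.add_nodes_from(ecs)
        g.add_edges_from(zip(ecs[:-1], ecs[1:]))
        return g

    def test_full_chain_up(self):
        g = self._chain(list("ABC"))
        runs = pw.find_coordinated_runs(g, {"A": 1, "B": 2, "C": 3}, min_len=3)
        assert [(r.ecs, r.direction) for r in runs] == [(("A", "B", "C"), "up")]
        assert runs[0].mean_abs_aefc == pytest.approx(2.0)

    def test_sign_flip_breaks_run(self):
        g = self._chain(list("ABC"))
        runs = pw.find_coordinated_runs(g, {"A": 1, "B": -2, "C": 3}, min_len=3)
        assert runs == []

    def test_five_node_mixed_signs(self):
        g = self._chain(list("ABCDE"))
        vals = {"A": 1, "B": 1, "C": 1, "D": -1, "E": -1}
        runs = pw.find_coordinated_runs(g, vals, min_len=2)
        assert [(r.ecs, r.direction) for r in runs] == [
            (("A", "B", "C"), "up"),
            (("D", "E"), "down"),
        ]

    def test_missing_value_breaks_run(self):
        g = self._chain(list("ABCD"))
        runs = pw.find_coordinated_runs(g, {"A": 1, "B": 1, "D": 1}, min_len=2)
        assert [r.ecs for r in runs] == [("A", "B")]

    def test_runs_maximal_and_sign_homogeneous(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(12, 0.25, seed=1, directed=True)
        g = nx.relabel_nodes(g, {i: f"E{i}" for i in g.nodes})
        g = nx.DiGraph(g.edges)
        vals = {n: float(rng.choice([-2, -1, 1, 2])) for n in g.nodes}
        sign_sub = {
            s: g.subgraph([n for n in g if np.sign(vals.get(n, 0)) == s])
            for s in (1, -1)
        }
        runs = pw.find_coordinated_runs(g, vals, min_len=1)
        for run in runs:
            signs = {np.sign(vals[ec]) for ec in run.ecs}
            assert len(signs) == 1
            sub = sign_sub[int(signs.pop())]
            # verify the path exists and is not extendable at either end
            for u, v in zip(run.ecs[:-1], run.ecs[1:]):
                assert sub.has_edge(u, v)
            head_preds = set(sub.predecessors(run.ecs[0])) - set(run.ecs)
            tail_succs = set(sub.successors(run.ecs[-1])) - set(run.ecs)
            if nx.is_directed_acyclic_graph(sub):
                assert not head_preds and not tail_succs

    def test_cycle_reported_with_warning(self):
        g = nx.DiGraph([("A", "B"), ("B", "C"), ("C", "A")])
        with pytest.warns(UserWarning, match="cyclic"):
            runs = pw.find_coordinated_runs(g, {"A": 1, "B": 1, "C": 1}, min_len=3)
        assert runs and runs[0].length == 3


class TestTaxonTally:
    def test_counts_and_conservation(self):
        matrix = pd.DataFrame(
            {
                "taxA": [1.0, -2.0, np.nan, 0.5],
                "taxB": [np.nan] * 4,
            },
            index=["e1", "e2", "e3", "e4"],
        ).rename_axis("ec")
        tally = pw.taxon_direction_tally(["e1", "e2", "e3", "e4"], matrix)
        assert tally.loc["taxA"].tolist() == [2, 1, 1]
        assert tally.loc["taxB"].tolist() == [0, 0, 4]
        assert (tally.sum(axis=1) == 4).all()

    def test_missing_ec_raises(self):
        matrix = pd.DataFrame({"t": [1.0]}, index=["e1"])
        with pytest.raises(KeyError):
            pw.taxon_direction_tally(["e1", "eX"], matrix)


def test_export_cytoscape(tmp_path):
    g = nx.DiGraph([("1.1.1.1", "2.2.2.2")])
    g.add_node("3.3.3.3")
    paths = pw.export_cytoscape(g, {"1.1.1.1": 2.5}, {"1.1.1.1"}, tmp_path / "net")
    sif = paths["sif"].read_text()
    assert "1.1.1.1\treaction\t2.2.2.2" in sif
    assert "3.3.3.3" in sif
    back = nx.read_graphml(paths["graphml"])
    assert back.nodes["1.1.1.1"]["significant"] is True
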