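"""Graph construction, Brandes betweenness vs an exhaustive path-counting
oracle, and the topological screens (main ingredients, PPI hubs, CTP)."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from phytonet.network_core import (
    TypedGraph,
    build_compound_target_network,
    build_ctp_network,
    build_ppi_network,
    centrality,
    hub_genes,
    screen_main_ingredients,
    summarize,
)
from phytonet.target_assembly import GeneSet
from oracles import brute_force_betweenness


def graph_from_edges(edges, roles=None):
    tg = TypedGraph()
    for a, b in edges:
        tg.add_node(a, (roles or {}).get(a, "target"))
        tg.add_node(b, (roles or {}).get(b, "target"))
        tg.add_edge(a, b)
    return tg


def gs(label, genes):
    return GeneSet.from_iterable(label, genes)


class TestTypedGraph:
    def test_self_loop_rejected(self):
        tg = TypedGraph()
        tg.add_node("a", "target")
        with pytest.raises(ValueError):
            tg.add_edge("a", "a")

    def test_duplicate_edges_collapse(self):
        tg = graph_from_edges([("a", "b"), ("a", "b")])
        assert tg.n_edges == 1

    def test_role_conflict_rejected(self):
        tg = TypedGraph()
        tg.add_node("x", "compound")
        with pytest.raises(ValueError):
            tg.add_node("x", "target")

    def test_bipartite_check(self):
        tg = TypedGraph()
        tg.add_node("c", "compound")
        tg.add_node("t", "target")
        tg.add_node("t2", "target")
        tg.add_edge("c", "t")
        tg.add_edge("t", "t2")
        with pytest.raises(ValueError):
            tg.assert_bipartite()


class TestCompoundTargetNetwork:
    def test_hand_drawn(self):
        # 2 compounds sharing 1 of 3 targets -> 5 nodes, 4 edges
        per = {"c1": gs("c1", ["T1", "T2"]), "c2": gs("c2", ["T2", "T3"])}
        tg = build_compound_target_network(per, gs("t", ["T1", "T2", "T3"]))
        assert tg.n_nodes == 5 and tg.n_edges == 4
        tg.assert_bipartite()

    def test_unlinked_compounds_omitted(self):
        per = {"c1": gs("c1", ["T1"]), "c2": gs("c2", ["X1"])}
        tg = build_compound_target_network(per, gs("t", ["T1"]))
        assert tg.nodes("compound") == ["c1"]

    def test_all_outside_therapeutic_is_empty(self):
        per = {"c1": gs("c1", ["X1", "X2"])}
        tg = build_compound_target_network(per, gs("t", ["T1"]))
        assert tg.n_nodes == 0 and tg.n_edges == 0

    def test_handshake(self, small_study):
        from phytonet.target_assembly import (intersect_targets, merge_sources,
                                              screen_disease_targets,
                                              screen_predictions)
        per, union, _ = screen_predictions(small_study.predictions)
        per_source, _ = screen_disease_targets(small_study.disease)
        therapeutic = intersect_targets(union, merge_sources(per_source))
        tg = build_compound_target_network(per, therapeutic)
        assert sum(tg.degree(n) for n in tg.nodes()) == 2 * tg.n_edges
        role_sum = summarize(tg)
        assert role_sum.role_mean_degree["compound"] * role_sum.role_counts[
            "compound"] == pytest.approx(tg.n_edges)


class TestCentrality:
    def test_star_center(self):
        tg = graph_from_edges([("c", "a"), ("c", "b"), ("c", "d")])
        table = centrality(tg).set_index("node")
        assert table.loc["c", "betweenness"] == pytest.approx(1.0)
        assert table.loc["a", "betweenness"] == 0.0

    def test_path_midpoint(self):
        tg = graph_from_edges([("a", "b"), ("b", "c")])
        table = centrality(tg).set_index("node")
        assert table.loc["b", "betweenness"] == pytest.approx(1.0)

    def test_tiny_graph_zero(self):
        tg = graph_from_edges([("a", "b")])
        assert set(centrality(tg)["betweenness"]) == {0.0}

    @pytest.mark.parametrize("seed", range(10))
    def test_er_fixture_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(2**31)))
        tg = TypedGraph()
        for n in g.nodes:
            tg.add_node(str(n), "target")
        for a, b in g.edges:
            tg.add_edge(str(a), str(b))
        expected = brute_force_betweenness(nx.relabel_nodes(g, str))
        table = centrality(tg).set_index("node")
        for node, val in expected.items():
            assert table.loc[node, "betweenness"] == pytest.approx(val, abs=1e-12)

    def test_betweenness_in_unit_interval(self, small_study):
        from phytonet.target_assembly import screen_predictions
        per, union, _ = screen_predictions(small_study.predictions)
        tg = build_compound_target_network(per, union)
        assert centrality(tg)["betweenness"].between(0, 1).all()


class TestMainIngredientScreen:
    def test_uniform_compounds_nothing_exceeds_mean(self):
        per = {f"c{i}": gs("x", [f"T{i}"]) for i in range(4)}
        tg = build_compound_target_network(per, gs("t", [f"T{i}" for i in range(4)]))
        selected, mean_deg, _ = screen_main_ingredients(tg)
        assert selected == set() and mean_deg == 1.0

    def test_disjoint_stars_degree_screen(self):
        per = {
            "c1": gs("x", ["A1"]),
            "c2": gs("x", ["B1"]),
            "c3": gs("x", [f"C{i}" for i in range(10)]),
        }
        therapeutic = gs("t", ["A1", "B1"] + [f"C{i}" for i in range(10)])
        tg = build_compound_target_network(per, therapeutic)
        selected, mean_deg, _ = screen_main_ingredients(tg)
        assert mean_deg == pytest.approx(4.0)
        assert selected <= {"c3"}

    def test_relabeling_invariance(self, small_study):
        from phytonet.target_assembly import screen_predictions
        per, union, _ = screen_predictions(small_study.predictions)
        tg = build_compound_target_network(per, union)
        selected, *_ = screen_main_ingredients(tg)
        relabeled = {f"z_{c}": genes for c, genes in per.items()}
        tg2 = build_compound_target_network(relabeled, union)
        selected2, *_ = screen_main_ingredients(tg2)
        assert {f"z_{c}" for c in selected} == selected2


class TestPPINetwork:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "combined_score"])

    def test_boundary_inclusive(self):
        edges = self.frame([("A", "B", 0.95), ("B", "C", 0.9), ("C", "D", 0.89)])
        tg = build_ppi_network(edges, gs("t", "ABCD"), 0.9)
        assert tg.n_edges == 2

    def test_free_genes_removed(self):
        edges = self.frame([("A", "B", 0.95), ("C", "D", 0.5)])
        tg = build_ppi_network(edges, gs("t", "ABCD"), 0.9)
        assert set(tg.nodes()) == {"A", "B"}

    def test_threshold_above_one_empty(self):
        edges = self.frame([("A", "B", 0.95)])
        with pytest.raises(ValueError):
            build_ppi_network(edges, gs("t", "AB"), 1.1)

    def test_self_interaction_rejected(self):
        with pytest.raises(ValueError):
            build_ppi_network(self.frame([("A", "A", 0.95)]), gs("t", "A"))

    def test_raising_threshold_monotone(self, small_study):
        genes = gs("t", small_study.truth["planted_intersection"])
        lo = build_ppi_network(small_study.ppi, genes, 0.5)
        hi = build_ppi_network(small_study.ppi, genes, 0.95)
        assert hi.n_edges <= lo.n_edges and hi.n_nodes <= lo.n_nodes
        assert set(hi.g.edges) <= set(lo.g.edges) | {(b, a) for a, b in lo.g.edges}


class TestHubGenes:
    def star(self, degrees):
        tg = TypedGraph()
        for g in degrees:
            tg.add_node(g, "target")
        leaf = 0
        for g, d in degrees.items():
            for _ in range(d):
                tg.add_node(f"L{leaf}", "target")
                tg.add_edge(g, f"L{leaf}")
                leaf += 1
        return tg

    def test_top_k(self):
        tg = self.star({"A": 3, "B": 2, "C": 1})
        top, overflow = hub_genes(tg, 2)
        assert [g for g, _ in top] == ["A", "B"]

    def test_tie_overflow_reported(self):
        tg = self.star({"A": 5, "B": 5, "C": 5})
        top, overflow = hub_genes(tg, 2)
        assert [g for g, _ in top] == ["A", "B"]
        assert [g for g, _ in overflow] == ["C"]

    def test_k_larger_than_graph(self):
        tg = self.star({"A": 1})
        top, overflow = hub_genes(tg, 10)
        assert len(top) == tg.n_nodes and overflow == []


class TestCtpAndSummary:
    def test_hand_built(self):
        per = {"c1": gs("x", ["T1", "T2"]), "c2": gs("x", ["T3"])}
        tg = build_compound_target_network(per, gs("t", ["T1", "T2", "T3"]))
        membership = {"P1": gs("P1", ["T1", "T2"])}
        ctp = build_ctp_network(tg, membership, ["P1"])
        # c2's only target is outside the pathway -> dropped with T3
        assert set(ctp.nodes("compound")) == {"c1"}
        assert set(ctp.nodes("target")) == {"T1", "T2"}
        assert set(ctp.nodes("pathway")) == {"P1"}
        assert ctp.n_edges == 4

    def test_empty_pathways_empty_graph(self):
        per = {"c1": gs("x", ["T1"])}
        tg = build_compound_target_network(per, gs("t", ["T1"]))
        ctp = build_ctp_network(tg, {}, [])
        assert ctp.n_nodes == 0

    def test_unknown_pathway_rejected(self):
        per = {"c1": gs("x", ["T1"])}
        tg = build_compound_target_network(per, gs("t", ["T1"]))
        with pytest.raises(ValueError):
            build_ctp_network(tg, {}, ["missing"])

    def test_summary_arithmetic(self):
        per = {"c1": gs("x", ["T1", "T2"]), "c2": gs("x", ["T2"])}
        tg = build_compound_target_network(per, gs("t", ["T1", "T2"]))
        s = summarize(tg)
        assert s.n_nodes == 4 and s.n_edges == 3
        assert s.mean_degree == pytest.approx(2 * 3 / 4)
        assert s.role_mean_degree["compound"] == pytest.approx(1.5)

    def test_single_node_zero_mean(self):
        tg = TypedGraph()
        tg.add_node("a", "target")
        assert summarize(tg).mean_degree == 0.0
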