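"""Hierarchy scoring, reachability, dominance, layering and cascades."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senet import (
    GenConfig,
    UndefinedScoreError,
    assign_layers,
    cascade,
    compare_positions,
    dominance,
    dominance_all,
    generate,
    krackhardt_hierarchy,
    reachability,
)

from conftest import closure_matrix, hierarchy_bruteforce, random_digraph


def digraph(arcs, nodes=()):
    graph = nx.DiGraph()
    graph.add_nodes_from(nodes)
    graph.add_edges_from(arcs)
    return graph


class TestKrackhardtHierarchy:
    def test_path_and_any_dag_score_one(self):
        assert krackhardt_hierarchy(digraph([("a", "b"), ("b", "c")])) == 1.0
        dag = digraph([("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")])
        assert krackhardt_hierarchy(dag) == 1.0

    def test_two_cycle_scores_zero(self):
        assert krackhardt_hierarchy(digraph([("a", "b"), ("b", "a")])) == 0.0

    def test_mixed_graph_scores_two_thirds(self):
        # {a,b} symmetric; {a,c} and {b,c} asymmetric (b reaches c via a)
        graph = digraph([("a", "b"), ("b", "a"), ("a", "c")])
        assert krackhardt_hierarchy(graph) == pytest.approx(2 / 3)

    def test_arc_free_graph_is_undefined(self):
        with pytest.raises(UndefinedScoreError):
            krackhardt_hierarchy(digraph([], nodes=["a", "b"]))

    def test_isolated_nodes_do_not_dilute_the_reachable_universe(self):
        graph = digraph([("a", "b"), ("b", "c")], nodes=["x", "y"])
        assert krackhardt_hierarchy(graph) == 1.0
        # with the all-pairs universe the same graph scores differently
        cyc = digraph([("a", "b"), ("b", "a")], nodes=["x"])
        assert krackhardt_hierarchy(cyc, pair_universe="all") == pytest.approx(1 - 1 / 3)
        assert krackhardt_hierarchy(cyc) == 0.0

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bruteforce_closure_on_random_digraphs(self, seed):
        rng = np.random.default_rng(seed)
        graph = random_digraph(int(rng.integers(2, 9)), int(rng.integers(1, 14)), seed)
        expected = hierarchy_bruteforce(graph)
        if expected is None:
            with pytest.raises(UndefinedScoreError):
                krackhardt_hierarchy(graph)
        else:
            assert krackhardt_hierarchy(graph) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(15))
    def test_adding_a_reverse_arc_never_raises_the_score(self, seed):
        graph = random_digraph(6, 8, seed + 100)
        if graph.number_of_edges() == 0:
            return
        base = hierarchy_bruteforce(graph)
        for u, v in list(graph.edges):
            if graph.has_edge(v, u):
                continue
            augmented = graph.copy()
            augmented.add_edge(v, u)
            assert krackhardt_hierarchy(augmented) <= base + 1e-12

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.integers(0, 5)).filter(
                lambda uv: uv[0] != uv[1]
            ),
            min_size=1,
            max_size=15,
        )
    )
    def test_score_matches_oracle_on_arbitrary_small_digraphs(self, arcs):
        graph = digraph([(f"n{u}", f"n{v}") for u, v in arcs],
                        nodes=[f"n{i}" for i in range(6)])
        expected = hierarchy_bruteforce(graph)
        assert expected is not None  # at least one arc, hence one reachable pair
        assert krackhardt_hierarchy(graph) == pytest.approx(expected)
        # and any DAG among the draws must score exactly 1
        if nx.is_directed_acyclic_graph(graph):
            assert krackhardt_hierarchy(graph) == 1.0

    def test_symmetrized_graph_scores_zero(self):
        graph = random_digraph(7, 10, 3)
        sym = graph.copy()
        sym.add_edges_from([(v, u) for u, v in graph.edges])
        assert krackhardt_hierarchy(sym) == 0.0


class TestReachability:
    def test_path_and_cycle(self):
        reach = reachability(digraph([("a", "b"), ("b", "c")]))
        assert reach["a"] == {"b", "c"}
        assert reach["c"] == set()
        cyc = reachability(digraph([("a", "b"), ("b", "c"), ("c", "a")]))
        # every distinct ordered pair is reachable around the cycle
        assert all(cyc[n] == {"a", "b", "c"} - {n} for n in "abc")

    def test_equals_matrix_power_closure_on_a_seeded_graph(self):
        graph = random_digraph(8, 12, seed=42)
        reach = reachability(graph)
        nodes, matrix = closure_matrix(graph)
        idx = {n: i for i, n in enumerate(nodes)}
        for u in nodes:
            for v in nodes:
                if u != v:
                    assert (v in reach[u]) == matrix[idx[u], idx[v]]


class TestDominance:
    def test_path_source_reaches_all_and_sink_none(self):
        graph = digraph([("a", "b"), ("b", "c"), ("c", "d")])
        assert dominance(graph, "a") == 3
        assert dominance(graph, "d") == 0

    def test_unknown_node_raises(self):
        with pytest.raises(KeyError):
            dominance(digraph([("a", "b")]), "ghost")

    def test_invariant_under_transitively_implied_arcs(self):
        graph = digraph([("a", "b"), ("b", "c")])
        before = dominance_all(graph)
        graph.add_edge("a", "c")  # already implied by reachability
        assert dominance_all(graph) == before


class TestLayers:
    @pytest.mark.parametrize("seed", range(10))
    def test_layer_zero_is_exactly_the_dominance_argmax(self, seed):
        graph = random_digraph(7, 9, seed + 300)
        dom = dominance_all(graph)
        layers = assign_layers(graph, dom)
        top = max(dom.values())
        assert {n for n, d in layers.items() if d == 0} == {
            n for n, v in dom.items() if v == top
        }
        assert all(d >= 0 for d in layers.values())

    def test_cycles_are_condensed_before_depth_assignment(self):
        graph = digraph([("a", "b"), ("b", "a"), ("a", "c"), ("c", "d")])
        layers = assign_layers(graph)
        assert layers["a"] == 0 and layers["b"] == 0  # one SCC at the top
        assert layers["c"] == 1 and layers["d"] == 2

    def test_chains_unreachable_from_the_top_sit_below(self):
        graph = digraph([("a", "b"), ("b", "c"), ("d", "e")])
        layers = assign_layers(graph)
        assert layers["a"] == 0
        assert layers["d"] > 0
        assert layers["e"] > layers["d"]


class TestCascade:
    def test_rights_preset_on_fixture_is_fully_hierarchical(self, example_network):
        result = cascade(example_network, "rights")
        assert result.selection == frozenset({"Right", "Action"})
        assert result.hierarchy == 1.0

    def test_native_farmer_man_dominates_the_rights_cascade(self, example_network):
        result = cascade(example_network, "rights")
        top = max(result.dominance, key=result.dominance.get)
        assert top == "native_farmer_man"
        assert result.layers["native_farmer_man"] == 0

    def test_benefits_fixture_has_one_reciprocated_reachable_pair(self, example_network):
        """The stylized benefits cascade is near-hierarchical: the land-animals
        pasture/manure loop is its single symmetric reachable pair, so the
        score equals 1 - 1/R with R counted by the brute-force closure."""
        result = cascade(example_network, "benefits")
        nodes, matrix = closure_matrix(result.graph)
        n_conn = n_sym = 0
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if matrix[i, j] or matrix[j, i]:
                    n_conn += 1
                    if matrix[i, j] and matrix[j, i]:
                        n_sym += 1
        assert n_sym == 1
        assert result.hierarchy == pytest.approx(1 - 1 / n_conn)
        assert result.hierarchy > 0.98

    def test_women_top_the_benefits_cascade_socially(self, example_network):
        result = cascade(example_network, "benefits")
        ranking = result.ranking(social_only=True)
        top_two = ranking.index[:2].tolist()
        genders = [example_network.nodes[n].gender for n in top_two]
        assert genders == ["female", "female"]

    def test_empty_selection_rejected_and_arcfree_selection_undefined(self, example_network):
        with pytest.raises(ValueError):
            cascade(example_network, frozenset())
        result = cascade(example_network, {"Payment"})
        # Payment links exist, so pick a selection with none at any level
        net = generate(GenConfig(seed=1, p_recip=0.0,
                                 p_type={"Transfer": 1.0}))
        empty = cascade(net, {"Right"})
        assert empty.hierarchy is None
        assert not empty.hierarchy_defined
        assert result.hierarchy is not None


class TestComparePositions:
    def test_identical_cascades_give_identical_rank_columns(self, example_network):
        a = cascade(example_network, "rights")
        table = compare_positions(a, a)
        assert (table["rank_a"] == table["rank_b"]).all()

    def test_roster_mismatch_is_rejected(self, example_network):
        a = cascade(example_network, "rights")
        other = generate(GenConfig(seed=0))
        b = cascade(other, "rights")
        with pytest.raises(ValueError):
            compare_positions(a, b)

    def test_passive_actors_sit_at_the_bottom_of_both_cascades(self, example_network):
        """Pastoralists, youths, traders, consumers, visitors and people in
        hardship originate no rights or benefits link in the fixture, so they
        must occupy the bottom ranks of both columns."""
        a = cascade(example_network, "rights")
        b = cascade(example_network, "benefits")
        table = compare_positions(a, b, social_only=True)
        passive = {
            "pastoralist_man", "pastoralist_woman", "migrant_youth",
            "trader", "consumer", "visitor", "person_in_hardship",
        }
        # bottom block = everything below the last positive-dominance node
        # (zero-dominance ties are broken lexicographically)
        n_active_a = int((table["dominance_a"] > 0).sum())
        n_active_b = int((table["dominance_b"] > 0).sum())
        for node in passive:
            assert table.loc[node, "dominance_a"] == 0
            assert table.loc[node, "dominance_b"] == 0
            assert table.loc[node, "rank_a"] > n_active_a
            assert table.loc[node, "rank_b"] > n_active_b

    def test_rights_top_is_low_in_benefits(self, example_network):
        a = cascade(example_network, "rights")
        b = cascade(example_network, "benefits")
        table = compare_positions(a, b, social_only=True)
        assert table.loc["native_farmer_man", "rank_a"] == 1
        assert table.loc["native_farmer_man", "rank_b"] > 2
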