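"""Kruskal maximum-weight forest and tree partitioning."""

import itertools
import random

import networkx as nx
import pytest

from conftest import make_graph, make_proteomes, make_table
from plastclust import (
    AlgorithmParams,
    max_weight_forest,
    partition_forest,
    preservation_criterion,
    run_pipeline,
)


def brute_force_max_forest_weight(g: nx.Graph) -> float:
    """Exhaustive maximum over all acyclic edge subsets (positive weights)."""
    edges = list(g.edges(data="weight"))
    best = 0.0
    n = g.number_of_nodes()
    for k in range(1, n):
        for subset in itertools.combinations(edges, k):
            h = nx.Graph()
            h.add_weighted_edges_from(subset)
            if nx.is_forest(h):
                best = max(best, sum(w for _, _, w in subset))
    return best


def test_forest_on_triangle_keeps_two_heaviest_edges():
    g = make_graph(
        [("a", "b", 0.9), ("b", "c", 0.8), ("a", "c", 0.5)],
        {"a": "A", "b": "B", "c": "C"},
    )
    forest = max_weight_forest(g)
    weights = sorted(w for _, _, w in forest.edges(data="weight"))
    assert weights == [0.8, 0.9]
    assert sum(weights) == pytest.approx(1.7)


def test_forest_on_edgeless_graph_is_all_singleton_trees():
    g = make_graph([], {f"n{i}": "A" for i in range(5)})
    forest = max_weight_forest(g)
    assert forest.number_of_nodes() == 5
    assert forest.number_of_edges() == 0


def test_forest_weight_matches_bruteforce_on_small_graphs():
    rng = random.Random(11)
    for _ in range(25):
        n = rng.randint(2, 7)
        nodes = {f"n{i}": f"P{i % 3}" for i in range(n)}
        edges = [
            (u, v, round(rng.uniform(0.01, 1.0), 4))
            for u, v in itertools.combinations(sorted(nodes), 2)
            if rng.random() < 0.5
        ]
        g = make_graph(edges, nodes)
        forest = max_weight_forest(g)
        assert nx.is_forest(forest)
        got = sum(w for _, _, w in forest.edges(data="weight"))
        assert got == pytest.approx(brute_force_max_forest_weight(g))


def test_forest_is_deterministic():
    g = make_graph(
        [("a1", "b1", 0.5), ("a1", "a2", 0.5), ("a2", "b1", 0.5)],
        {"a1": "A", "a2": "A", "b1": "B"},
    )
    e1 = set(map(frozenset, max_weight_forest(g).edges))
    e2 = set(map(frozenset, max_weight_forest(g).edges))
    assert e1 == e2
    # equal weights: the same-proteome edge is considered first
    assert frozenset({"a1", "a2"}) in e1


# --- preservation criterion ---------------------------------------------------

def test_criterion_false_when_same_proteome_nodes_disconnected():
    # a1 -0.9- b1 -0.3- a2: min edge spans proteomes but a1, a2 only meet via b1
    t = make_graph(
        [("a1", "b1", 0.9), ("b1", "a2", 0.3)],
        {"a1": "A", "a2": "A", "b1": "B"},
    )
    assert preservation_criterion(t) is False


def test_criterion_true_for_star_with_adjacent_same_proteome_nodes():
    t = make_graph(
        [("a1", "a2", 0.9), ("a1", "b1", 0.4), ("a1", "c1", 0.8)],
        {"a1": "A", "a2": "A", "b1": "B", "c1": "C"},
    )
    # min edge a1-b1 spans proteomes; A-nodes {a1, a2} are adjacent
    assert preservation_criterion(t) is True


def test_criterion_false_when_min_edge_within_proteome():
    t = make_graph(
        [("a1", "a2", 0.3), ("a1", "b1", 0.9)],
        {"a1": "A", "a2": "A", "b1": "B"},
    )
    assert preservation_criterion(t) is False


def test_criterion_undefined_for_single_node_tree():
    t = make_graph([], {"a1": "A"})
    with pytest.raises(ValueError):
        preservation_criterion(t)


# --- partitioning -------------------------------------------------------------

def _partition(graph, H=0.6, use_criterion=True):
    forest = max_weight_forest(graph)
    return partition_forest(forest, AlgorithmParams(H=H), use_criterion=use_criterion)


def test_partition_splits_path_at_subthreshold_edge():
    g = make_graph(
        [("a1", "b1", 0.9), ("b1", "a2", 0.3)],
        {"a1": "A", "a2": "A", "b1": "B"},
    )
    c = _partition(g)
    assert c.clusters == [frozenset({"a1", "b1"})]
    assert c.singletons == ["a2"]


def test_partition_preserves_path_when_min_edge_above_threshold():
    g = make_graph(
        [("a1", "b1", 0.9), ("b1", "a2", 0.7)],
        {"a1": "A", "a2": "A", "b1": "B"},
    )
    c = _partition(g)
    assert c.clusters == [frozenset({"a1", "a2", "b1"})]
    assert c.singletons == []


def test_partition_splits_at_subthreshold_same_proteome_edge():
    # min edge joins two proteins of one proteome: condition (1) fails
    g = make_graph(
        [("a1", "a2", 0.3), ("a1", "b1", 0.9), ("a2", "c1", 0.8)],
        {"a1": "A", "a2": "A", "b1": "B", "c1": "C"},
    )
    c = _partition(g)
    assert sorted(sorted(cl) for cl in c.clusters) == [["a1", "b1"], ["a2", "c1"]]


def test_partition_result_independent_of_worklist_order():
    rng = random.Random(3)
    nodes = {f"n{i}": f"P{i % 4}" for i in range(14)}
    edges = [
        (u, v, round(rng.random(), 3))
        for u, v in itertools.combinations(sorted(nodes), 2)
        if rng.random() < 0.25
    ]
    g = make_graph(edges, nodes)
    forest = max_weight_forest(g)
    whole = partition_forest(forest, AlgorithmParams())
    # partition each tree separately: trees never interact
    parts_sep: list[frozenset] = []
    singles_sep: list[str] = []
    for comp in nx.connected_components(forest):
        sub = partition_forest(forest.subgraph(comp).copy(), AlgorithmParams())
        parts_sep.extend(sub.clusters)
        singles_sep.extend(sub.singletons)
    assert sorted(whole.clusters, key=min) == sorted(parts_sep, key=min)
    assert sorted(whole.singletons) == sorted(singles_sep)


def test_partition_count_monotone_in_threshold_without_criterion():
    rng = random.Random(5)
    nodes = {f"n{i}": f"P{i % 3}" for i in range(12)}
    edges = [
        (u, v, round(rng.random(), 3))
        for u, v in itertools.combinations(sorted(nodes), 2)
        if rng.random() < 0.3
    ]
    g = make_graph(edges, nodes)
    counts = []
    for H in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
        c = _partition(g, H=H, use_criterion=False)
        counts.append(len(c.clusters) + len(c.singletons))
    assert counts == sorted(counts)


def test_every_output_tree_is_above_threshold_or_preserved():
    rng = random.Random(9)
    nodes = {f"n{i}": f"P{i % 3}" for i in range(12)}
    edges = [
        (u, v, round(rng.random(), 3))
        for u, v in itertools.combinations(sorted(nodes), 2)
        if rng.random() < 0.3
    ]
    g = make_graph(edges, nodes)
    forest = max_weight_forest(g)
    params = AlgorithmParams()
    c = partition_forest(forest, params)
    # re-derive each cluster's subtree from the forest and check the disjunction
    for cluster in c.clusters:
        sub = forest.subgraph(cluster)
        min_w = min(w for _, _, w in sub.edges(data="weight"))
        assert min_w >= params.H or preservation_criterion(sub)


# --- end-to-end ---------------------------------------------------------------

def test_pipeline_minimal_positive_case():
    proteomes = make_proteomes({"A": [("a1", "MA")], "B": [("b1", "MA")]})
    table = make_table(
        {"A|a1": 100.0, "B|b1": 100.0}, [("A|a1", "B|b1", 90.0, 1e-12)]
    )
    clustering, report = run_pipeline(proteomes, table)
    assert clustering.clusters == [frozenset({"A|a1", "B|b1"})]
    assert clustering.singletons == []
    assert report["n_clusters"] == 1 and report["n_singletons"] == 0


def test_pipeline_all_pairs_failing_expect_yields_singletons():
    proteomes = make_proteomes({"A": [("a1", "MA")], "B": [("b1", "MA")]})
    table = make_table(
        {"A|a1": 100.0, "B|b1": 100.0}, [("A|a1", "B|b1", 90.0, 0.5)]
    )
    clustering, report = run_pipeline(proteomes, table)
    assert clustering.clusters == []
    assert sorted(clustering.singletons) == ["A|a1", "B|b1"]
    assert report["isolated_nodes"] == 2
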