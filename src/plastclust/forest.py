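"""Maximum-weight spanning forest and threshold-driven tree partitioning.

Kruskal's procedure is run on the sparse graph with edges in descending
weight order; among equal weights, edges joining proteins of the same
proteome come first, then lexicographic endpoint order for determinism.
The resulting forest is then partitioned: each tree's minimum-weight edge
is removed — splitting the tree in two — whenever its weight falls below
the threshold H *and* the tree fails the preservation criterion.  The
criterion keeps a tree whole when (1) its minimum-weight edge joins
proteins of different proteomes and (2) every proteome's nodes within the
tree induce a connected subtree.  Output trees of size ≥ 2 are the protein
clusters; size-1 trees are singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .graph import build_base_graph, sparsify
from .io import CLUSTER_PREFIX, SINGLETON_PREFIX, Proteome
from .similarity import AlgorithmParams, RawScoreTable

__all__ = [
    "Clustering",
    "max_weight_forest",
    "partition_forest",
    "preservation_criterion",
    "run_pipeline",
]


@dataclass
class Clustering:
    """Final partition into clusters (size ≥ 2) and singletons."""

    clusters: list[frozenset[str]]
    singletons: list[str]
    params_used: AlgorithmParams = field(default_factory=AlgorithmParams)

    def __post_init__(self) -> None:
        # deterministic order: clusters by their smallest member id
        self.clusters = sorted(
            (frozenset(c) for c in self.clusters), key=lambda c: min(c)
        )
        self.singletons = sorted(self.singletons)

    @property
    def n_proteins(self) -> int:
        return sum(len(c) for c in self.clusters) + len(self.singletons)

    def parts(self) -> Iterator[tuple[str, frozenset[str]]]:
        """Yield (part_id, members) with C/S-prefixed deterministic ids."""
        width = max(4, len(str(max(len(self.clusters), len(self.singletons), 1))))
        for i, c in enumerate(self.clusters, 1):
            yield f"{CLUSTER_PREFIX}{i:0{width}d}", c
        for i, s in enumerate(self.singletons, 1):
            yield f"{SINGLETON_PREFIX}{i:0{width}d}", frozenset([s])

    def cluster_of(self) -> dict[str, str]:
        """Map every protein id to its part id."""
        return {pid: part_id for part_id, members in self.parts() for pid in members}

    def params_comment(self) -> str:
        p = self.params_used
        return f"plastclust H={p.H} E={p.E} L={p.L} scorer={p.scorer}"


def _kruskal_edge_key(graph: nx.Graph):
    def key(edge: tuple[str, str]) -> tuple:
        u, v = sorted(edge)
        w = graph.edges[u, v]["weight"]
        same = graph.nodes[u]["proteome"] == graph.nodes[v]["proteome"]
        # descending weight; equal weights: same-proteome edges first;
        # then lexicographic endpoints for determinism
        return (-w, 0 if same else 1, u, v)

    return key


def max_weight_forest(sparse: nx.Graph) -> nx.Graph:
    """Kruskal maximum-weight spanning forest of the sparse graph.

    Contains every node; an edge is added iff it creates no cycle.  With
    positive weights the result attains the maximum total weight over all
    forests in the graph.
    """
    forest = nx.Graph(role="forest")
    forest.add_nodes_from(sparse.nodes(data=True))
    uf = nx.utils.UnionFind(sparse.nodes)
    for u, v in sorted(sparse.edges, key=_kruskal_edge_key(sparse)):
        if uf[u] != uf[v]:
            uf.union(u, v)
            forest.add_edge(u, v, **sparse.edges[u, v])
    return forest


def _min_weight_edge(tree: nx.Graph) -> tuple[str, str]:
    """Minimum-weight edge; ties broken lexicographically by endpoints."""
    return min(
        (tuple(sorted(e)) for e in tree.edges),
        key=lambda e: (tree.edges[e]["weight"], e),
    )


def preservation_criterion(
    tree: nx.Graph, proteome_of: Mapping[str, str] | None = None
) -> bool:
    """Whether a tree is preserved despite a minimum edge below H.

    True iff (1) the tree's minimum-weight edge joins proteins of different
    proteomes, and (2) for every proteome, the tree nodes belonging to it
    induce a connected subtree (any two same-proteome proteins are linked
    through proteins of that proteome only).  Undefined for single-node
    trees (callers handle those upstream).
    """
    if tree.number_of_edges() == 0:
        raise ValueError("preservation criterion undefined for single-node trees")
    if proteome_of is None:
        proteome_of = {n: tree.nodes[n]["proteome"] for n in tree.nodes}
    u, v = _min_weight_edge(tree)
    if proteome_of[u] == proteome_of[v]:
        return False
    by_proteome: dict[str, list[str]] = {}
    for n in tree.nodes:
        by_proteome.setdefault(proteome_of[n], []).append(n)
    for nodes in by_proteome.values():
        if len(nodes) > 1 and not nx.is_connected(tree.subgraph(nodes)):
            return False
    return True


def partition_forest(
    forest: nx.Graph,
    params: AlgorithmParams,
    use_criterion: bool = True,
) -> Clustering:
    """Split forest trees at sub-threshold minimum edges into the final parts.

    Worklist procedure over the trees of the forest; a tree whose minimum
    edge weighs less than H and which fails the preservation criterion is
    split at that edge, and both halves re-enter the worklist.  The result
    does not depend on worklist order (trees never interact).
    ``use_criterion=False`` disables the preservation criterion (every
    sub-threshold minimum edge is cut), useful for diagnostics.
    """
    clusters: list[frozenset[str]] = []
    singletons: list[str] = []
    work: list[nx.Graph] = [
        forest.subgraph(c).copy() for c in nx.connected_components(forest)
    ]
    while work:
        tree = work.pop()
        if tree.number_of_nodes() == 1:
            singletons.append(next(iter(tree.nodes)))
            continue
        e = _min_weight_edge(tree)
        if tree.edges[e]["weight"] < params.H and not (
            use_criterion and preservation_criterion(tree)
        ):
            tree.remove_edge(*e)
            for comp in nx.connected_components(tree):
                work.append(tree.subgraph(comp).copy())
        else:
            clusters.append(frozenset(tree.nodes))
    return Clustering(clusters=clusters, singletons=singletons, params_used=params)


def run_pipeline(
    proteomes: Iterable[Proteome],
    scores: RawScoreTable,
    params: AlgorithmParams | None = None,
) -> tuple[Clustering, dict]:
    """Base graph → sparse graph → Kruskal forest → partition.

    Returns the clustering and a run report with the stage statistics:
    protein/node counts, edge counts of both graphs, isolated-node count,
    singletons added during partitioning, and cluster count.
    """
    if params is None:
        params = AlgorithmParams()
    proteomes = list(proteomes)
    base = build_base_graph(scores, proteomes, params)
    sparse = sparsify(base, params)
    forest = max_weight_forest(sparse)
    clustering = partition_forest(forest, params)

    isolated = sum(1 for n in sparse.nodes if sparse.degree(n) == 0)
    n_components_nonsingleton = sum(
        1 for c in nx.connected_components(sparse) if len(c) > 1
    )
    report = {
        "n_proteomes": len(proteomes),
        "n_proteins": base.number_of_nodes(),
        "base_edges": base.number_of_edges(),
        "sparse_edges": sparse.number_of_edges(),
        "non_isolated_nodes": sparse.number_of_nodes() - isolated,
        "isolated_nodes": isolated,
        "sparse_components_nonsingleton": n_components_nonsingleton,
        "forest_weight": sum(w for _, _, w in forest.edges(data="weight")),
        "n_clusters": len(clustering.clusters),
        "n_singletons": len(clustering.singletons),
        "singletons_added_by_partition": len(clustering.singletons) - isolated,
        "params": {"H": params.H, "E": params.E, "L": params.L, "scorer": params.scorer},
    }
    return clustering, report
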