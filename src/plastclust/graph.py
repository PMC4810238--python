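"""Similarity graphs: the base graph and its bidirectional-maximum sparse form.

The base graph has one node per protein (isolated proteins included) and an
edge for every scored pair whose expect value passes the threshold E, the
edge weight being the normalized similarity.  The sparse graph keeps an
edge between proteins of proteomes i and k only when it is simultaneously
the maximum-weight edge from its endpoint in proteome i to any protein of
proteome k and vice versa — a generalization of the bidirectional best hit
— and its weight is at least the floor L.  For a within-proteome edge
(i = k) only one maximum condition applies: the edge must be the best
within-proteome edge at one of its endpoints.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import networkx as nx

from .io import Proteome
from .similarity import AlgorithmParams, RawScoreTable

__all__ = ["build_base_graph", "sparsify", "export_edges"]


def build_base_graph(
    scores: RawScoreTable,
    proteomes: Iterable[Proteome],
    params: AlgorithmParams,
) -> nx.Graph:
    """Build the base graph under the expect threshold.

    Nodes: every protein of every proteome (isolated ones retained — they
    surface later as singletons).  Edge (p, q) present iff a scored pair
    exists with expect ≤ params.E; weight = normalized similarity.  Loops
    are not allowed by construction (the score table holds no self pairs).
    """
    g = nx.Graph(role="base")
    for pm in proteomes:
        for p in pm:
            g.add_node(p.protein_id, proteome=p.proteome_id)
    for (a, b), (raw, expect) in scores.entries.items():
        if expect > params.E:
            continue
        if a not in g or b not in g:
            raise ValueError(f"scored pair ({a!r}, {b!r}) not among input proteins")
        g.add_edge(a, b, weight=scores.similarity(a, b), raw=raw, expect=expect)
    return g


def sparsify(base: nx.Graph, params: AlgorithmParams) -> nx.Graph:
    """Keep only bidirectional per-proteome-pair maximum edges with weight ≥ L.

    For an edge (u, v) with u in proteome i and v in proteome k (i ≠ k) the
    weight must equal both max_m s(u, P_km) and max_m s(P_im, v), maxima
    over base-graph edges between the two proteomes; ties keep every edge
    achieving the maximum.  For i = k the edge is kept when it achieves the
    within-proteome incident maximum at either endpoint.  Node set (and any
    isolated node) is preserved.
    """
    sparse = nx.Graph(role="sparse")
    sparse.add_nodes_from(base.nodes(data=True))

    # best[u][k] = max weight among u's base edges into proteome k
    best: dict[str, dict[str, float]] = {u: {} for u in base.nodes}
    for u, v, w in base.edges(data="weight"):
        pu = base.nodes[u]["proteome"]
        pv = base.nodes[v]["proteome"]
        bu = best[u]
        if w > bu.get(pv, float("-inf")):
            bu[pv] = w
        bv = best[v]
        if w > bv.get(pu, float("-inf")):
            bv[pu] = w

    for u, v, data in base.edges(data=True):
        w = data["weight"]
        if w < params.L:
            continue
        pu = base.nodes[u]["proteome"]
        pv = base.nodes[v]["proteome"]
        if pu != pv:
            keep = w == best[u][pv] and w == best[v][pu]
        else:
            keep = w == best[u][pu] or w == best[v][pv]
        if keep:
            sparse.add_edge(u, v, **data)
    return sparse


def export_edges(graph: nx.Graph, path: str | Path) -> None:
    """Write an edge-list TSV (protein1, protein2, raw_score, expect, s)."""
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\traw_score\texpect\tnormalized_similarity\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            d = graph.edges[u, v]
            raw = "" if d.get("raw") is None else format(d["raw"], "g")
            expect = "" if d.get("expect") is None else format(d["expect"], "g")
            fh.write(f"{u}\t{v}\t{raw}\t{expect}\t{d['weight']:.6g}\n")
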