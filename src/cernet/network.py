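"""ceRNA network assembly, centrality analysis and pivotal-node screening.

Correlation edges are cross-referenced against a candidate interaction table
(both orientation-free); surviving edges form an undirected simple tripartite
graph over DE genes. Degree, betweenness (unnormalized shortest-path pair
counts, breadth-first accumulation) and closeness (Wasserman-Faust
component-scaled) are computed on the full graph, and the pivotal set is the
three-way intersection of the per-metric top-k sets with inclusive ties.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import InteractionTable, pair_class_for

CENTRALITY_COLUMNS = [
    "node",
    "rna_class",
    "degree",
    "betweenness",
    "closeness",
    "rank_degree",
    "rank_betweenness",
    "rank_closeness",
]

#: sponge-consistent correlation signs per pair class
SIGN_RULES = {"lncRNA-miRNA": -1, "miRNA-mRNA": -1, "lncRNA-mRNA": +1}


def cross_reference(
    correlation_edges: pd.DataFrame, interactions: InteractionTable
) -> pd.DataFrame:
    """Keep correlation edges whose unordered pair and class match the table."""
    if correlation_edges.empty:
        return correlation_edges.copy()
    keep = [
        interactions.has(
            row.gene_a, row.gene_b, pair_class_for(row.class_a, row.class_b)
        )
        for row in correlation_edges.itertuples()
    ]
    out = correlation_edges[keep].copy()
    out["provenance"] = "correlation+database"
    return out


def assemble_network(
    edges: pd.DataFrame, de_records: pd.DataFrame, sign_filter: bool = True
) -> nx.Graph:
    """Build the undirected tripartite graph from surviving edges.

    With ``sign_filter`` on, edges violating sponge-consistency are dropped
    (lncRNA-miRNA and miRNA-mRNA must be negatively, lncRNA-mRNA positively
    correlated). Every endpoint must have a DE record; node attributes carry
    RNA class and DE direction.
    """
    info = de_records.set_index("gene_id") if not de_records.empty else None
    graph = nx.Graph()
    for row in edges.itertuples():
        pair_class = pair_class_for(row.class_a, row.class_b)
        if sign_filter and np.sign(row.r) != SIGN_RULES[pair_class]:
            continue
        for gene, cls in ((row.gene_a, row.class_a), (row.gene_b, row.class_b)):
            if info is None or gene not in info.index:
                raise ValueError(f"edge endpoint {gene!r} has no DE record")
            graph.add_node(
                gene, rna_class=cls, direction=str(info.at[gene, "direction"])
            )
        graph.add_edge(
            row.gene_a,
            row.gene_b,
            pair_class=pair_class,
            r=float(row.r),
            p_value=float(row.p_value),
            provenance=getattr(row, "provenance", "correlation"),
        )
    return graph


def _bfs(adjacency: dict, source):
    """Shortest-path counts and BFS order from one source (unweighted)."""
    dist = {source: 0}
    sigma = {source: 1.0}
    order = []
    preds: dict = {source: []}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        order.append(v)
        for w in adjacency[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0.0
                preds[w] = []
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
                preds[w].append(v)
    return dist, sigma, preds, order


def degree_centrality(graph: nx.Graph) -> dict:
    """Incident-edge count per node."""
    return {node: int(deg) for node, deg in graph.degree()}


def betweenness_centrality(graph: nx.Graph) -> dict:
    """Unnormalized betweenness: per node, the sum over unordered pairs of the
    fraction of shortest paths passing through it (Brandes accumulation)."""
    adjacency = {v: list(graph.adj[v]) for v in graph.nodes}
    bc = dict.fromkeys(graph.nodes, 0.0)
    for source in graph.nodes:
        _, sigma, preds, order = _bfs(adjacency, source)
        delta = dict.fromkeys(order, 0.0)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != source:
                bc[w] += delta[w]
    # each unordered pair was accumulated from both endpoints
    return {v: b / 2.0 for v, b in bc.items()}


def closeness_centrality(graph: nx.Graph) -> dict:
    """Wasserman-Faust closeness: (c-1)/sum(d) scaled by (c-1)/(n-1) where c
    is the node's component size; isolated nodes score 0."""
    n = graph.number_of_nodes()
    adjacency = {v: list(graph.adj[v]) for v in graph.nodes}
    out = {}
    for v in graph.nodes:
        dist, _, _, _ = _bfs(adjacency, v)
        c = len(dist)
        total = sum(dist.values())
        if c <= 1 or total == 0 or n <= 1:
            out[v] = 0.0
        else:
            out[v] = ((c - 1) / total) * ((c - 1) / (n - 1))
    return out


def centrality_table(graph: nx.Graph) -> pd.DataFrame:
    """Per-node degree/betweenness/closeness with min-ranks (1 = highest)."""
    nodes = list(graph.nodes)
    if not nodes:
        return pd.DataFrame(columns=CENTRALITY_COLUMNS)
    deg = degree_centrality(graph)
    btw = betweenness_centrality(graph)
    clo = closeness_centrality(graph)

    def ranks(values):
        return rankdata([-values[v] for v in nodes], method="min").astype(int)

    return pd.DataFrame(
        {
            "node": nodes,
            "rna_class": [graph.nodes[v].get("rna_class", "") for v in nodes],
            "degree": [deg[v] for v in nodes],
            "betweenness": [btw[v] for v in nodes],
            "closeness": [clo[v] for v in nodes],
            "rank_degree": ranks(deg),
            "rank_betweenness": ranks(btw),
            "rank_closeness": ranks(clo),
        },
        columns=CENTRALITY_COLUMNS,
    )


@dataclass
class PivotalSet:
    """Top-k (inclusive ties) per metric and their three-way intersection."""

    k: int
    members: set[str]
    top_by_metric: dict[str, set[str]]


def pivotal_screen(centralities: pd.DataFrame, k: int = 10) -> PivotalSet:
    """Intersect the per-metric top-k node sets (ties at the k-th value kept)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if centralities.empty:
        return PivotalSet(k, set(), {m: set() for m in ("degree", "betweenness", "closeness")})
    top: dict[str, set[str]] = {}
    for metric in ("degree", "betweenness", "closeness"):
        values = centralities[metric].to_numpy()
        if k >= len(values):
            top[metric] = set(centralities["node"])
            continue
        threshold = np.sort(values)[::-1][k - 1]
        top[metric] = set(centralities["node"][values >= threshold])
    members = top["degree"] & top["betweenness"] & top["closeness"]
    return PivotalSet(k, members, top)
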