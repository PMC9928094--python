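"""Network- and node-level statistics for gene co-occurrence networks.

Conventions (chosen to match the igraph defaults common in microbial-network
studies, and documented because keystone ranking depends on them):

* density = m / C(n, 2) over the network's node set;
* clustering coefficient C = global transitivity, 3 * triangles / connected
  triples, 0 when no triple exists;
* average path length L = mean shortest-path length over mutually *reachable*
  unordered pairs only — intersection networks are often disconnected and
  unreachable pairs are excluded rather than imputed;
* betweenness is the raw (unnormalized) Brandes count of shortest paths
  through a node; closeness is 1 / (sum of distances to nodes in the same
  connected component); normalized degree divides by (n - 1);
* modules come from Girvan-Newman edge-betweenness removal with a
  deterministic lexicographic tie-break, cut at the partition maximizing
  Newman-Girvan modularity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import modularity

from .cooccurrence import GeneNetwork

logger = logging.getLogger(__name__)


@dataclass
class NetworkStats:
    """All Table-style statistics for one network."""

    n_nodes: int
    n_edges: int
    density: float
    clustering_coefficient: float
    avg_path_length: float
    modules: list[set]
    per_node: pd.DataFrame

    @property
    def n_modules(self) -> int:
        return len(self.modules)


def density(g: GeneNetwork) -> float:
    """Edges as a fraction of all possible edges, m / C(n, 2)."""
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError(f"density undefined for a network with {n} node(s)")
    return g.number_of_edges() / (n * (n - 1) / 2)


def transitivity_global(g: GeneNetwork) -> float:
    """Global clustering coefficient: 3 * triangles / connected triples."""
    return nx.transitivity(g)


def avg_path_length(g: GeneNetwork) -> float:
    """Mean shortest-path length over mutually reachable unordered pairs."""
    if g.number_of_edges() == 0:
        raise ValueError("average path length undefined for an edgeless network")
    total = 0
    count = 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            count += len(dists) - 1  # excludes the zero self-distance
    # each unordered pair counted twice
    return total / count


def node_centralities(g: GeneNetwork) -> pd.DataFrame:
    """Per-node betweenness, closeness and normalized degree.

    Betweenness is unnormalized; closeness is the reciprocal of the sum of
    within-component distances (0 for an isolated node); normalized degree is
    deg / (n - 1).
    """
    nodes = sorted(g.nodes)
    n = len(nodes)
    betw = nx.betweenness_centrality(g, normalized=False) if n else {}
    rows = []
    for v in nodes:
        dists = nx.single_source_shortest_path_length(g, v)
        dist_sum = sum(dists.values())
        rows.append(
            {
                "assay_id": v,
                "betweenness": betw[v],
                "closeness": 1.0 / dist_sum if dist_sum > 0 else 0.0,
                "normalized_degree": g.degree(v) / (n - 1) if n > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["assay_id", "betweenness", "closeness", "normalized_degree"]).set_index(
        "assay_id"
    )


def _canonical_partition(blocks) -> list[set]:
    return sorted((set(b) for b in blocks), key=lambda b: min(map(str, b)))


def communities_edge_betweenness(g: GeneNetwork) -> tuple[list[set], int]:
    """Girvan-Newman divisive clustering cut at maximum modularity.

    Edges of maximal betweenness are removed one at a time; when several tie,
    the lexicographically smallest (sorted endpoint pair) goes first, making
    the dendrogram deterministic.  Among the successive component partitions
    the one maximizing modularity on the *original* graph is returned;
    modularity ties resolve to the coarsest (earliest) partition.  An
    edgeless graph yields singleton modules.
    """
    if g.number_of_edges() == 0:
        part = _canonical_partition([{v} for v in g.nodes])
        return part, len(part)

    work = nx.Graph()
    work.add_nodes_from(g.nodes)
    work.add_edges_from(g.edges)
    partitions = [_canonical_partition(nx.connected_components(work))]
    while work.number_of_edges():
        eb = nx.edge_betweenness_centrality(work, normalized=False)
        mx = max(eb.values())
        tol = 1e-10 * max(1.0, mx)
        candidates = [tuple(sorted(e, key=str)) for e, v in eb.items() if v >= mx - tol]
        if len(candidates) > 1:
            logger.debug("edge-betweenness tie among %d edges; removing smallest", len(candidates))
        u, v = min(candidates)
        work.remove_edge(u, v)
        comps = _canonical_partition(nx.connected_components(work))
        if len(comps) > len(partitions[-1]):
            partitions.append(comps)

    best = max(partitions, key=lambda p: modularity(g, p))
    return best, len(best)


def stats_report(g: GeneNetwork) -> NetworkStats:
    """Aggregate all statistics for one network (n_nodes >= 2 required)."""
    if g.number_of_nodes() < 2:
        raise ValueError("statistics require a network with at least 2 nodes")
    modules, _ = communities_edge_betweenness(g)
    return NetworkStats(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        density=density(g),
        clustering_coefficient=transitivity_global(g),
        avg_path_length=avg_path_length(g),
        modules=modules,
        per_node=node_centralities(g),
    )
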