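"""Simplification, pairwise intersection and k-way consensus of gene networks.

Edge identity for intersection is the unordered node pair only; attribute
values (rho differs between parents by construction) do not participate.
Intersection edges carry the flat list of their ancestors' rho values
(``rho_parents``) and its mean (``rho`` / ``rho_mean``), which makes
``intersect_many`` associative and commutative in the resulting graph.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx

from .cooccurrence import GeneNetwork

logger = logging.getLogger(__name__)


def simplify(g: GeneNetwork) -> GeneNetwork:
    """Remove self-loops and degree-0 nodes; idempotent.

    networkx graphs cannot hold duplicate edges, so de-duplication is
    implicit; provenance (graph attributes) is preserved.
    """
    out = g.copy()
    out.remove_edges_from(nx.selfloop_edges(out))
    out.remove_nodes_from([v for v, d in out.degree() if d == 0])
    return out


def _parent_rhos(data: dict) -> list[float]:
    if "rho_parents" in data:
        return list(data["rho_parents"])
    if "rho" in data:
        return [data["rho"]]
    return []


def intersect(g1: GeneNetwork, g2: GeneNetwork) -> GeneNetwork:
    """Consensus of two networks: nodes and edges present in both.

    The result is simplified (no isolated nodes) and records both parents in
    its provenance.
    """
    out: GeneNetwork = nx.Graph()
    out.graph["parents"] = [g1.graph.get("network_id"), g2.graph.get("network_id")]
    shared_nodes = set(g1.nodes) & set(g2.nodes)
    out.add_nodes_from(shared_nodes)
    for u, v, d1 in g1.edges(data=True):
        if g2.has_edge(u, v):
            rhos = _parent_rhos(d1) + _parent_rhos(g2.edges[u, v])
            attrs = {"rho_parents": rhos}
            if rhos:
                mean = sum(rhos) / len(rhos)
                attrs["rho"] = mean
                attrs["rho_mean"] = mean
            out.add_edge(u, v, **attrs)
    return simplify(out)


def intersect_many(gs: Sequence[GeneNetwork]) -> GeneNetwork:
    """Left fold of :func:`intersect`; a single-element list is simplified.

    Any empty member makes the result empty (intersection is absorbing).
    """
    gs = list(gs)
    if not gs:
        raise ValueError("cannot intersect an empty list of networks")
    if len(gs) == 1:
        return simplify(gs[0])
    acc = gs[0]
    for g in gs[1:]:
        acc = intersect(acc, g)
    acc.graph["parents"] = [g.graph.get("network_id") for g in gs]
    return acc
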