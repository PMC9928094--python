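"""Pathway-stratified keystone-gene identification across a network series.

A keystone gene is an assay that, among its pathway's nodes present in a
network, attains the greatest value in at least two of {betweenness
centrality, closeness centrality, normalized node degree}.  Maxima are
evaluated within pathway and per network, with ties inclusive: in a
symmetric graph every co-maximal node is a keystone.  The rule is rank-based,
so keystone sets are invariant to any common rescaling of a measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cooccurrence import GeneNetwork
from .net_stats import node_centralities

logger = logging.getLogger(__name__)

MEASURES = ("betweenness", "closeness", "normalized_degree")
DEFAULT_PATHWAYS = frozenset({"nitrification", "denitrification"})


@dataclass
class KeystoneReport:
    """Keystone table over a series of networks plus the betweenness
    timeline used for plotting (absent-from-network cells are NaN, not 0)."""

    table: pd.DataFrame
    betweenness_timeline: pd.DataFrame


def _maximizers(values: pd.Series) -> set[str]:
    mx = values.max()
    tol = 1e-9 * max(1.0, abs(mx))
    return set(values.index[values >= mx - tol])


def identify_keystones(
    g: GeneNetwork,
    assays: pd.DataFrame,
    pathways: Iterable[str] = DEFAULT_PATHWAYS,
    centralities: pd.DataFrame | None = None,
    network_id: str | None = None,
) -> pd.DataFrame:
    """Keystone assays of one network, stratified by pathway.

    ``assays`` is an assay-metadata table indexed by assay_id with a
    ``pathway`` column.  Returns one row per keystone with its three
    centrality values and the measures it topped; a pathway with no node in
    the network contributes nothing.
    """
    if centralities is None:
        centralities = node_centralities(g)
    net_id = network_id or g.graph.get("network_id", "")
    rows = []
    for pathway in sorted(set(pathways)):
        members = [v for v in g.nodes if assays.loc[v, "pathway"] == pathway] if len(g) else []
        if not members:
            continue
        sub = centralities.loc[sorted(members)]
        tops: dict[str, set[str]] = {meas: _maximizers(sub[meas]) for meas in MEASURES}
        for assay in sub.index:
            topped = [meas for meas in MEASURES if assay in tops[meas]]
            if len(topped) >= 2:
                rows.append(
                    {
                        "network_id": net_id,
                        "pathway": pathway,
                        "assay_id": assay,
                        "betweenness": sub.loc[assay, "betweenness"],
                        "closeness": sub.loc[assay, "closeness"],
                        "normalized_degree": sub.loc[assay, "normalized_degree"],
                        "measures_topped": ",".join(topped),
                    }
                )
    cols = [
        "network_id",
        "pathway",
        "assay_id",
        "betweenness",
        "closeness",
        "normalized_degree",
        "measures_topped",
    ]
    return pd.DataFrame(rows, columns=cols)


def keystone_timeline(
    gs: Sequence[GeneNetwork],
    assays: pd.DataFrame,
    pathways: Iterable[str] = DEFAULT_PATHWAYS,
    network_ids: Sequence[str] | None = None,
) -> KeystoneReport:
    """Keystones per network over an ordered series, plus the assay x
    timepoint betweenness matrix.

    A cell is NaN (absent, not zero) when the assay is not a node of that
    network.
    """
    gs = list(gs)
    if not gs:
        raise ValueError("keystone_timeline requires at least one network")
    if network_ids is None:
        network_ids = [g.graph.get("network_id", f"network_{i + 1}") for i, g in enumerate(gs)]

    tables = []
    timeline = pd.DataFrame(index=sorted(assays.index), columns=list(network_ids), dtype=float)
    for net_id, g in zip(network_ids, gs):
        cent = node_centralities(g)
        tables.append(identify_keystones(g, assays, pathways, cent, network_id=net_id))
        for assay in cent.index:
            timeline.loc[assay, net_id] = cent.loc[assay, "betweenness"]
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    timeline = timeline.dropna(how="all")
    return KeystoneReport(table=table, betweenness_timeline=timeline)
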