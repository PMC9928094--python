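import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from ncycnet import AbundanceMatrix


def make_matrix(values, sample_ids=None, assay_ids=None, pathways=None, **kwargs):
    """Build a small AbundanceMatrix with auto-generated metadata."""
    arr = np.asarray(values, dtype=float)
    n, k = arr.shape
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    assay_ids = assay_ids or [f"a{j + 1}" for j in range(k)]
    pathways = pathways or ["nitrification"] * k
    samples = pd.DataFrame(
        {
            "location": ["siteX"] * n,
            "timepoint": [1] * n,
            "season": ["late_dry"] * n,
            "growth_stage": ["anthesis"] * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    assays = pd.DataFrame(
        {
            "gene_symbol": assay_ids,
            "pathway": pathways,
            "taxon_group": ["bacterial"] * k,
            "redundancy_group": [None] * k,
        },
        index=pd.Index(assay_ids, name="assay_id"),
    )
    return AbundanceMatrix(
        values=pd.DataFrame(arr, index=samples.index, columns=assays.index),
        samples=samples,
        assays=assays,
        **kwargs,
    )


def random_graph(rng, n_max=8):
    """A random simple graph with 2..n_max nodes and at least one edge."""
    n = int(rng.integers(2, n_max + 1))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for u, v in pairs:
        if rng.random() < 0.45:
            g.add_edge(u, v)
    if g.number_of_edges() == 0:
        u, v = pairs[int(rng.integers(len(pairs)))]
        g.add_edge(u, v)
    return g


@pytest.fixture
def toy_network():
    """Two triangles joined by a single bridge edge."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")])
    return g
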