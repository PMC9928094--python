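"""Spearman co-occurrence matrices and thresholded network construction.

Networks are built per grouping cell (location x timepoint): pairwise
Spearman rank correlations on pairwise-complete observations, two-sided
p-values from the t approximation, Benjamini-Hochberg FDR correction over
that cell's upper-triangle tests, then an edge for every assay pair passing
the joint criterion |rho| > rho_min and p < alpha (both strict).  Because the
statistic is rank-based, the resulting edge set is invariant to any strictly
monotone transform of the abundances — in particular identical on raw
copies per gram and on their log10.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import AbundanceMatrix

logger = logging.getLogger(__name__)

#: A co-occurrence network is a simple undirected networkx graph whose nodes
#: are assay ids, with edge attributes rho / p_raw / p_adj / sign and graph
#: attributes recording provenance (location, timepoint, criterion, parents).
GeneNetwork = nx.Graph


@dataclass(frozen=True)
class EdgeCriterion:
    """Joint strength + significance cutoff defining a co-occurrence edge.

    Defaults are the stringent values standard in gene co-occurrence work:
    |rho| > 0.75 and BH-adjusted p < 0.01, two-sided in sign.
    """

    rho_min: float = 0.75
    alpha: float = 0.01
    use_absolute: bool = True
    p_kind: str = "bh_adjusted"

    def __post_init__(self) -> None:
        if not 0.0 < self.rho_min < 1.0:
            raise ValueError(f"rho_min must be in (0, 1), got {self.rho_min}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.p_kind not in ("raw", "bh_adjusted"):
            raise ValueError(f"p_kind must be 'raw' or 'bh_adjusted', got {self.p_kind!r}")

    def to_dict(self) -> dict:
        return {
            "rho_min": self.rho_min,
            "alpha": self.alpha,
            "use_absolute": self.use_absolute,
            "p_kind": self.p_kind,
        }


@dataclass
class CorrelationResult:
    """Symmetric Spearman rho / raw p / BH-adjusted p matrices with per-pair
    complete-observation counts.  Masked pairs (too few complete pairs, or a
    constant column) are NaN in all three statistic matrices."""

    rho: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    n_pairs: pd.DataFrame

    @property
    def assay_ids(self) -> list[str]:
        return list(self.rho.index)

    def to_long(self) -> pd.DataFrame:
        """Long-format upper-triangle table: assay_a, assay_b, rho, p_raw,
        p_adj, n_pairs."""
        rows = []
        ids = self.assay_ids
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                rows.append(
                    {
                        "assay_a": a,
                        "assay_b": b,
                        "rho": self.rho.loc[a, b],
                        "p_raw": self.p_raw.loc[a, b],
                        "p_adj": self.p_adj.loc[a, b],
                        "n_pairs": self.n_pairs.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)


def adjust_pvalues_bh(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i} min(1, p_(j) * m / j) in sorted order, mapped back
    to the input order; monotone and >= the input elementwise.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(arr, method="fdr_bh")
    return adjusted


def spearman_matrix(matrix: AbundanceMatrix, min_pairs: int = 10) -> CorrelationResult:
    """Pairwise-complete Spearman correlation of all assay pairs.

    Ties are mid-ranked; p-values are two-sided from the t approximation
    t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom.  Pairs with
    fewer than ``min_pairs`` complete observations, or with a constant column
    among the complete observations, are masked (NaN) and never become edges.
    BH adjustment runs over the unmasked upper triangle only.
    """
    if matrix.n_assays < 2:
        raise ValueError("need at least 2 assays to correlate")
    if min_pairs < 4:
        raise ValueError(f"min_pairs must be >= 4, got {min_pairs}")

    ids = list(matrix.values.columns)
    k = len(ids)
    vals = matrix.values.to_numpy(dtype=float)
    rho = np.full((k, k), np.nan)
    p_raw = np.full((k, k), np.nan)
    n_pairs = np.zeros((k, k), dtype=int)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p_raw, 1.0)
    np.fill_diagonal(n_pairs, matrix.n_samples)

    triu: list[tuple[int, int]] = []
    triu_p: list[float] = []
    for i, j in itertools.combinations(range(k), 2):
        both = ~np.isnan(vals[:, i]) & ~np.isnan(vals[:, j])
        n = int(both.sum())
        n_pairs[i, j] = n_pairs[j, i] = n
        if n < min_pairs:
            continue
        x, y = vals[both, i], vals[both, j]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning(
                "constant assay column in complete pairs for (%s, %s); pair masked",
                ids[i],
                ids[j],
            )
            continue
        r, p = stats.spearmanr(x, y)
        rho[i, j] = rho[j, i] = r
        p_raw[i, j] = p_raw[j, i] = p
        triu.append((i, j))
        triu_p.append(p)

    p_adj = np.full((k, k), np.nan)
    np.fill_diagonal(p_adj, 1.0)
    if triu:
        adjusted = adjust_pvalues_bh(np.array(triu_p))
        for (i, j), q in zip(triu, adjusted):
            p_adj[i, j] = p_adj[j, i] = q

    as_df = lambda a: pd.DataFrame(a, index=ids, columns=ids)
    return CorrelationResult(as_df(rho), as_df(p_raw), as_df(p_adj), as_df(n_pairs))


def build_network(
    corr: CorrelationResult,
    criterion: EdgeCriterion = EdgeCriterion(),
    provenance: dict | None = None,
) -> GeneNetwork:
    """Threshold a correlation matrix into a co-occurrence network.

    An edge joins every unordered assay pair with |rho| > rho_min (rho >
    rho_min when ``use_absolute`` is False) and p < alpha under the chosen
    p_kind, both strict.  Nodes with no qualifying edge are excluded; an
    empty network is a valid result.
    """
    g: GeneNetwork = nx.Graph()
    g.graph["criterion"] = criterion.to_dict()
    g.graph.update(provenance or {})
    p_mat = corr.p_adj if criterion.p_kind == "bh_adjusted" else corr.p_raw
    ids = corr.assay_ids
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            r = corr.rho.loc[a, b]
            p = p_mat.loc[a, b]
            if np.isnan(r) or np.isnan(p):
                continue
            strength = abs(r) if criterion.use_absolute else r
            if strength > criterion.rho_min and p < criterion.alpha:
                g.add_edge(
                    a,
                    b,
                    rho=float(r),
                    p_raw=float(corr.p_raw.loc[a, b]),
                    p_adj=float(corr.p_adj.loc[a, b]),
                    sign=1 if r > 0 else -1,
                )
    return g
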