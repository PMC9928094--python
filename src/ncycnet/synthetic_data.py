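"""Synthetic HT-qPCR abundance data with known co-occurrence structure.

The generator emulates an N-cycle gene array campaign: 2 locations x 6
timepoints x 28 soil samples per cell (336 samples total) over 21 assays,
with block-correlated abundances, a seasonal schedule in which co-occurring
blocks are large in the dry-season timepoints and shrink through the rainy
season, and a small random fraction of non-detects (masked, not zeroed).

Latent draws are multivariate normal with correlation ``r_within`` inside a
block and ``r_between`` across blocks; abundances are the latent variables
mapped onto normal margins on the log10 copies-per-gram scale (a Gaussian
copula — for normal margins this is an affine map of the latent draw).
Rank-based inference is margin-free, so only the copula matters for network
recovery; the margins merely need to look like qPCR data (log10 copies
around 4-8).  For a bivariate normal pair with Pearson correlation r the
population Spearman correlation is (6/pi) * arcsin(r/2).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cooccurrence import GeneNetwork
from .data_model import AbundanceMatrix

logger = logging.getLogger(__name__)

Edge = frozenset

#: 21 N-cycle assays mirroring a NiCE-chip style panel (synthetic stand-in
#: panel: gene/taxon labels are field-typical, not a published primer list).
_DEFAULT_ASSAYS = [
    # assay_id, gene_symbol, pathway, taxon_group, redundancy_group
    ("Arch_amoA", "amoA", "nitrification", "AOA", None),
    ("Beta_amoA", "amoA", "nitrification", "AOB", None),
    ("Gamma_amoA_F2R1", "amoA", "nitrification", "AOB", None),
    ("Proteo_hao", "hao", "nitrification", "bacterial", None),
    ("Nitrobacter_nxrB", "nxrB", "nitrification", "bacterial", None),
    ("Nitrospira_nxrB", "nxrB", "nitrification", "bacterial", None),
    ("comaB", "amoA", "nitrification", "comammox", None),
    ("nirK_876", "nirK", "denitrification", "bacterial", "nirK_bact"),
    ("nirK_FlaCu", "nirK", "denitrification", "bacterial", "nirK_bact"),
    ("nirK_fungal", "nirK", "denitrification", "fungal", None),
    ("nirS_cd3aF", "nirS", "denitrification", "bacterial", "nirS_bact"),
    ("nirS_R3cd", "nirS", "denitrification", "bacterial", "nirS_bact"),
    ("nosZ_1F", "nosZ", "denitrification", "bacterial", "nosZ_I"),
    ("nosZ_912F", "nosZ", "denitrification", "bacterial", "nosZ_I"),
    ("napA_V17", "napA", "denitrification", "bacterial", None),
    ("narG_1960m2", "narG", "denitrification", "bacterial", None),
    ("nrfA_F1", "nrfA", "dnra", "bacterial", "nrfA"),
    ("nrfA_F2", "nrfA", "dnra", "bacterial", "nrfA"),
    ("nifH_IGK3", "nifH", "fixation", "bacterial", "nifH"),
    ("nifH_PolF", "nifH", "fixation", "bacterial", "nifH"),
    ("hzo_cl1F1", "hzo", "anammox", "bacterial", None),
]

#: Block sizes per timepoint: dense dry-season blocks, sparser rainy-season.
_BLOCK_SIZES = {1: [7, 6, 4], 2: [6, 4], 3: [5, 4], 4: [5, 3], 5: [4, 3], 6: [3, 2]}

_SEASONS = {1: "late_dry", 2: "late_dry", 3: "mid_rainy", 4: "mid_rainy", 5: "late_rainy", 6: "late_rainy"}


def default_assay_table(n_assays: int = 21) -> pd.DataFrame:
    """Assay metadata table for the synthetic panel (indexed by assay_id)."""
    if not 2 <= n_assays <= len(_DEFAULT_ASSAYS):
        raise ValueError(f"n_assays must be in [2, {len(_DEFAULT_ASSAYS)}]")
    frame = pd.DataFrame(
        _DEFAULT_ASSAYS[:n_assays],
        columns=["assay_id", "gene_symbol", "pathway", "taxon_group", "redundancy_group"],
    )
    return frame.set_index("assay_id")


def default_block_schedule(
    assay_ids: list[str], locations: list[str], timepoints: list[int]
) -> dict[tuple[str, int], list[list[str]]]:
    """Seasonal block map: consecutive assays grouped into blocks whose sizes
    shrink with timepoint; the second location omits the last member of the
    first block, so location-intersections differ from per-cell truth."""
    block_map: dict[tuple[str, int], list[list[str]]] = {}
    for tp in timepoints:
        sizes = _BLOCK_SIZES.get(tp, [3, 2])
        blocks: list[list[str]] = []
        start = 0
        for s in sizes:
            if start + s > len(assay_ids):
                break
            blocks.append(list(assay_ids[start : start + s]))
            start += s
        for li, loc in enumerate(locations):
            loc_blocks = [list(b) for b in blocks]
            if li > 0 and len(loc_blocks[0]) > 2:
                loc_blocks[0] = loc_blocks[0][:-1]
            block_map[(loc, tp)] = loc_blocks
    return block_map


@dataclass
class SynthConfig:
    """Generator settings; defaults reproduce the emulated study layout."""

    n_locations: int = 2
    n_timepoints: int = 6
    samples_per_cell: int = 28
    n_assays: int = 21
    block_map: dict | None = None  # (location, timepoint) -> list of assay-id blocks
    r_within: float = 0.9
    r_between: float = 0.0
    margin_mean: float = 6.0
    margin_sd: float = 0.5
    nondetect_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.nondetect_rate < 1.0:
            raise ValueError(f"nondetect_rate must be in [0, 1), got {self.nondetect_rate}")
        if not -1.0 < self.r_within < 1.0 or not -1.0 < self.r_between < 1.0:
            raise ValueError("latent correlations must lie in (-1, 1)")

    @property
    def locations(self) -> list[str]:
        return [f"site_{chr(ord('a') + i)}" for i in range(self.n_locations)]

    @property
    def timepoints(self) -> list[int]:
        return list(range(1, self.n_timepoints + 1))


@dataclass
class GroundTruth:
    """True co-occurring pairs: per grouping cell, and their per-timepoint
    intersection across locations."""

    cell_edges: dict  # (location, timepoint) -> set of frozenset pairs
    timepoint_edges: dict  # timepoint -> set of frozenset pairs


def _block_edges(blocks: list[list[str]]) -> set:
    edges = set()
    for block in blocks:
        edges.update(Edge(p) for p in itertools.combinations(block, 2))
    return edges


def _cell_correlation(assay_ids: list[str], blocks: list[list[str]], r_within: float, r_between: float) -> np.ndarray:
    k = len(assay_ids)
    corr = np.full((k, k), r_between)
    idx = {a: i for i, a in enumerate(assay_ids)}
    for block in blocks:
        for a, b in itertools.combinations(block, 2):
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r_within
    np.fill_diagonal(corr, 1.0)
    eigmin = np.linalg.eigvalsh(corr).min()
    if eigmin < -1e-8:
        raise ValueError(
            f"block specification {blocks!r} implies a non-PSD correlation matrix "
            f"(min eigenvalue {eigmin:.3g})"
        )
    return corr


def generate(config: SynthConfig) -> tuple[AbundanceMatrix, GroundTruth]:
    """Draw a full synthetic abundance matrix and its ground-truth edges.

    Per cell the latent multivariate normal is transformed onto normal
    margins (margin_mean, margin_sd) on the log10 copies-per-gram scale;
    a ``nondetect_rate`` fraction of cells is masked at random.  Fully
    reproducible from ``config.seed``.
    """
    assays = default_assay_table(config.n_assays)
    assay_ids = list(assays.index)
    block_map = config.block_map
    if block_map is None:
        block_map = default_block_schedule(assay_ids, config.locations, config.timepoints)

    rng = np.random.default_rng(config.seed)
    frames = []
    meta_rows = []
    cell_edges = {}
    for loc in config.locations:
        for tp in config.timepoints:
            blocks = block_map.get((loc, tp), [])
            corr = _cell_correlation(assay_ids, blocks, config.r_within, config.r_between)
            # small jitter guards Cholesky against an exactly singular corr
            chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(assay_ids)))
            z = rng.standard_normal((config.samples_per_cell, len(assay_ids))) @ chol.T
            vals = config.margin_mean + config.margin_sd * z
            if config.nondetect_rate > 0:
                vals[rng.random(vals.shape) < config.nondetect_rate] = np.nan
            ids = [f"{loc}_t{tp}_s{i + 1:03d}" for i in range(config.samples_per_cell)]
            frames.append(pd.DataFrame(vals, index=ids, columns=assay_ids))
            season = _SEASONS.get(tp, "unknown")
            stage = "anthesis" if tp % 2 == 1 else "regrowth"
            meta_rows.extend(
                {
                    "sample_id": sid,
                    "location": loc,
                    "timepoint": tp,
                    "season": season,
                    "growth_stage": stage,
                }
                for sid in ids
            )
            cell_edges[(loc, tp)] = _block_edges(blocks)

    values = pd.concat(frames)
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    matrix = AbundanceMatrix(values=values, samples=samples, assays=assays)

    timepoint_edges = {}
    for tp in config.timepoints:
        sets = [cell_edges[(loc, tp)] for loc in config.locations]
        timepoint_edges[tp] = set.intersection(*sets) if sets else set()
    return matrix, GroundTruth(cell_edges=cell_edges, timepoint_edges=timepoint_edges)


@dataclass(frozen=True)
class RecoveryScore:
    precision: float  # NaN when inferred empty but truth nonempty (undefined)
    recall: float
    tp: int
    fp: int
    fn: int


def evaluate_recovery(inferred: GeneNetwork | set, truth: set) -> RecoveryScore:
    """Precision/recall of an inferred edge set against ground truth.

    ``inferred`` may be a network or a set of frozenset pairs.  Empty
    inferred + empty truth scores precision 1; empty inferred against a
    nonempty truth leaves precision undefined (NaN).  Empty truth scores
    recall 1.
    """
    if isinstance(inferred, set):
        inferred_edges = {Edge(e) for e in inferred}
    else:
        inferred_edges = {Edge((u, v)) for u, v in inferred.edges}
    truth_edges = {Edge(e) for e in truth}
    tp = len(inferred_edges & truth_edges)
    fp = len(inferred_edges - truth_edges)
    fn = len(truth_edges - inferred_edges)
    if inferred_edges:
        precision = tp / len(inferred_edges)
    else:
        precision = 1.0 if not truth_edges else math.nan
    recall = tp / len(truth_edges) if truth_edges else 1.0
    return RecoveryScore(precision=precision, recall=recall, tp=tp, fp=fp, fn=fn)
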