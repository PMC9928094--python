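"""End-to-end orchestration: per-cell networks -> per-timepoint location
intersections -> global consensus -> statistics, null comparison, keystones.

The default workflow mirrors the emulated study design: one co-occurrence
network per (location, timepoint) cell (12 with the default 2 x 6 layout),
an intersection across locations at each timepoint (6), and a single global
consensus intersecting the per-timepoint networks.  Every stochastic step is
seeded from the single configured seed, so a rerun with the same
configuration is byte-identical in all outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cooccurrence import CorrelationResult, EdgeCriterion, GeneNetwork, build_network, spearman_matrix
from .data_model import AbundanceMatrix, filter_assays, read_abundance_table, write_abundance_table
from .graph_ops import intersect_many, simplify
from .keystone import DEFAULT_PATHWAYS, KeystoneReport, keystone_timeline
from .net_stats import NetworkStats, stats_report
from .null_models import NullEnsembleResult, SmallWorldReport, null_ensemble, response_ratios
from .synthetic_data import GroundTruth, SynthConfig, generate

logger = logging.getLogger(__name__)

_STATS_COLUMNS = [
    "network_id",
    "season",
    "n_nodes",
    "n_edges",
    "n_modules",
    "density",
    "c_obs",
    "c_random_mean",
    "c_random_sd",
    "l_obs",
    "l_random_mean",
    "l_random_sd",
    "rr",
    "lrr",
    "c_quantile",
    "reps",
    "seed",
]
_ROUNDED = ["density", "c_obs", "c_random_mean", "c_random_sd", "l_obs", "l_random_mean", "l_random_sd", "rr", "lrr"]


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run.

    Either the three input paths or ``synth`` must be provided.  All
    thresholds default to the stringent co-occurrence criterion
    (|rho| > 0.75, BH-adjusted p < 0.01).
    """

    abundance: str | None = None
    sample_meta: str | None = None
    assay_meta: str | None = None
    synth: SynthConfig | None = None
    criterion: EdgeCriterion = field(default_factory=EdgeCriterion)
    min_pairs: int = 10
    min_detect_fraction: float = 0.5
    null_reps: int = 1000
    seed: int = 0
    group_cols: tuple[str, str] = ("location", "timepoint")
    intersect_by: str = "location"
    pathways: tuple[str, ...] = tuple(sorted(DEFAULT_PATHWAYS))
    outdir: str = "ncycnet_out"

    def __post_init__(self) -> None:
        if self.abundance is None and self.synth is None:
            raise ValueError("configure either input paths or a synthetic-data block")
        if self.abundance is not None and (self.sample_meta is None or self.assay_meta is None):
            raise ValueError("abundance input requires sample_meta and assay_meta paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "criterion" in raw:
            raw["criterion"] = EdgeCriterion(**raw["criterion"])
        if "synth" in raw and raw["synth"] is not None:
            raw["synth"] = SynthConfig(**raw["synth"])
        if "group_cols" in raw:
            raw["group_cols"] = tuple(raw["group_cols"])
        if "pathways" in raw:
            raw["pathways"] = tuple(raw["pathways"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["criterion"] = self.criterion.to_dict()
        if self.synth is not None:
            synth = dataclasses.asdict(self.synth)
            synth.pop("block_map", None)  # not yaml-serializable; defaults regenerate it
            raw["synth"] = synth
        raw["group_cols"] = list(self.group_cols)
        raw["pathways"] = list(self.pathways)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class PipelineResult:
    """In-memory bundle of everything one run produced."""

    matrix: AbundanceMatrix
    truth: GroundTruth | None
    cell_networks: dict
    cell_correlations: dict
    timepoint_networks: dict
    consensus: GeneNetwork
    stats_table: pd.DataFrame
    keystones: KeystoneReport | None
    manifest: dict


def _derive_seed(seed: int, index: int) -> int:
    return (seed * 1_000_003 + 7919 * (index + 1)) % (2**31)


def export_network(
    g: GeneNetwork, fmt: str, path: str | Path, assays: pd.DataFrame | None = None
) -> None:
    """Write a network as GraphML or edge-list TSV.

    GraphML carries node pathway/taxon annotations (when an assay table is
    given) and all scalar edge attributes; list- or dict-valued attributes
    are flattened to strings for portability.
    """
    path = Path(path)
    if fmt == "graphml":
        out = nx.Graph()
        out.add_nodes_from(g.nodes)
        if g.number_of_nodes() == 0:
            logger.warning("exporting empty network to %s", path)
        if assays is not None:
            for v in out.nodes:
                if v in assays.index:
                    out.nodes[v]["pathway"] = str(assays.loc[v, "pathway"])
                    out.nodes[v]["taxon_group"] = str(assays.loc[v, "taxon_group"])
        for u, v, d in g.edges(data=True):
            clean = {}
            for key, val in d.items():
                if isinstance(val, (list, tuple)):
                    clean[key] = ",".join(f"{x:.12g}" for x in val)
                elif val is not None:
                    clean[key] = val
            out.add_edge(u, v, **clean)
        for key, val in g.graph.items():
            out.graph[key] = json.dumps(val) if isinstance(val, (dict, list)) else val
        nx.write_graphml(out, path)
    elif fmt == "edgelist_tsv":
        rows = []
        net_id = g.graph.get("network_id", "")
        for u, v, d in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            a, b = sorted((str(u), str(v)))
            rows.append(
                {
                    "assay_a": a,
                    "assay_b": b,
                    "rho_mean": d.get("rho_mean", d.get("rho", np.nan)),
                    "sign": d.get("sign", 1),
                    "network_id": net_id,
                }
            )
        pd.DataFrame(rows, columns=["assay_a", "assay_b", "rho_mean", "sign", "network_id"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network export format {fmt!r}")


def read_network_edgelist(path: str | Path) -> GeneNetwork:
    """Read an edge-list TSV written by :func:`export_network`."""
    frame = pd.read_csv(path, sep="\t")
    g: GeneNetwork = nx.Graph()
    for _, row in frame.iterrows():
        g.add_edge(row["assay_a"], row["assay_b"], rho=row["rho_mean"], sign=int(row["sign"]))
        if isinstance(row.get("network_id"), str):
            g.graph["network_id"] = row["network_id"]
    return g


def _fmt2(x) -> str:
    return "" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.2f}"


def write_stats_table(
    entries: list[tuple[str, str, NetworkStats, SmallWorldReport | None, NullEnsembleResult | None]],
    path: str | Path,
) -> pd.DataFrame:
    """Write the per-network statistics CSV (observed + null + RR columns).

    Each full-precision column in density..lrr gets a 2-decimal companion
    column (suffix ``_2dp``) mirroring conventional table formatting.  Input
    order is preserved.
    """
    if not entries:
        raise ValueError("no statistics entries to write")
    rows = []
    for network_id, season, stats, sw, null in entries:
        row = {
            "network_id": network_id,
            "season": season,
            "n_nodes": stats.n_nodes,
            "n_edges": stats.n_edges,
            "n_modules": stats.n_modules,
            "density": stats.density,
            "c_obs": stats.clustering_coefficient,
            "l_obs": stats.avg_path_length,
            "c_random_mean": null.c_mean if null else np.nan,
            "c_random_sd": null.c_sd if null else np.nan,
            "l_random_mean": null.l_mean if null else np.nan,
            "l_random_sd": null.l_sd if null else np.nan,
            "rr": sw.rr if sw and sw.rr is not None else np.nan,
            "lrr": sw.lrr if sw and sw.lrr is not None else np.nan,
            "c_quantile": sw.c_quantile if sw else np.nan,
            "reps": null.reps if null else 0,
            "seed": null.seed if null else 0,
        }
        rows.append(row)
    frame = pd.DataFrame(rows, columns=_STATS_COLUMNS)
    for col in _ROUNDED:
        frame[f"{col}_2dp"] = frame[col].map(_fmt2)
    frame.to_csv(path, index=False)
    return frame


def load_input(config: PipelineConfig) -> tuple[AbundanceMatrix, GroundTruth | None]:
    if config.synth is not None:
        matrix, truth = generate(config.synth)
        return matrix, truth
    matrix = read_abundance_table(config.abundance, config.sample_meta, config.assay_meta)
    return matrix, None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow and write the output bundle to
    ``config.outdir``."""
    outdir = Path(config.outdir)
    (outdir / "networks").mkdir(parents=True, exist_ok=True)

    matrix, truth = load_input(config)
    matrix = filter_assays(matrix, config.min_detect_fraction)
    if config.synth is not None:
        write_abundance_table(
            matrix,
            outdir / "abundance.csv",
            outdir / "sample_meta.csv",
            outdir / "assay_meta.csv",
        )

    loc_col, time_col = config.group_cols

    cell_networks: dict[tuple, GeneNetwork] = {}
    cell_correlations: dict[tuple, CorrelationResult] = {}
    for key, sub in matrix.iter_cells(by=config.group_cols):
        loc, tp = key
        net_id = f"cell_{loc}_t{tp}"
        try:
            corr = spearman_matrix(sub, min_pairs=config.min_pairs)
        except ValueError as exc:
            raise RuntimeError(f"correlation stage failed for network {net_id}: {exc}") from exc
        g = build_network(
            corr,
            config.criterion,
            provenance={"location": str(loc), "timepoint": int(tp), "network_id": net_id},
        )
        g = simplify(g)
        if g.number_of_edges() == 0:
            logger.warning("network %s is empty under the edge criterion", net_id)
        cell_networks[key] = g
        cell_correlations[key] = corr

    timepoints = sorted({tp for (_, tp) in cell_networks})
    timepoint_networks: dict = {}
    for tp in timepoints:
        members = [g for (loc, t), g in sorted(cell_networks.items(), key=lambda kv: str(kv[0])) if t == tp]
        inter = intersect_many(members)
        inter.graph["network_id"] = f"intersection_t{tp}"
        inter.graph["timepoint"] = int(tp)
        if inter.number_of_edges() == 0:
            logger.warning("intersection at timepoint %s is empty", tp)
        timepoint_networks[tp] = inter

    consensus = intersect_many([timepoint_networks[tp] for tp in timepoints])
    consensus.graph["network_id"] = "consensus"

    # --- statistics + null comparison on the per-timepoint intersections ---
    season_of = (
        matrix.samples.drop_duplicates(subset=[time_col])
        .set_index(time_col)["season"]
        .to_dict()
        if "season" in matrix.samples.columns
        else {}
    )
    entries = []
    for idx, tp in enumerate(timepoints):
        g = timepoint_networks[tp]
        net_id = g.graph["network_id"]
        if g.number_of_edges() == 0:
            logger.warning("skipping statistics for empty network %s", net_id)
            continue
        stats = stats_report(g)
        null = null_ensemble(
            n=stats.n_nodes,
            m=stats.n_edges,
            reps=config.null_reps,
            seed=_derive_seed(config.seed, idx),
        )
        sw = response_ratios(stats.clustering_coefficient, null, stats.avg_path_length)
        entries.append((net_id, str(season_of.get(tp, "")), stats, sw, null))
    stats_frame = (
        write_stats_table(entries, outdir / "stats.csv") if entries else pd.DataFrame(columns=_STATS_COLUMNS)
    )

    # --- keystones on the non-empty per-timepoint intersections ---
    keystones = None
    nonempty = [(tp, g) for tp, g in timepoint_networks.items() if g.number_of_nodes()]
    if nonempty:
        keystones = keystone_timeline(
            [g for _, g in nonempty],
            matrix.assays,
            pathways=config.pathways,
            network_ids=[g.graph["network_id"] for _, g in nonempty],
        )
        keystones.table.to_csv(outdir / "keystones.csv", index=False)
        timeline = keystones.betweenness_timeline.copy()
        timeline.index.name = "assay_id"
        timeline.to_csv(outdir / "betweenness_timeline.csv")

    for key, g in cell_networks.items():
        loc, tp = key
        base = outdir / "networks" / f"cell_{loc}_t{tp}"
        export_network(g, "graphml", base.with_suffix(".graphml"), matrix.assays)
        export_network(g, "edgelist_tsv", base.with_suffix(".tsv"))
    for tp, g in timepoint_networks.items():
        base = outdir / "networks" / f"intersection_t{tp}"
        export_network(g, "graphml", base.with_suffix(".graphml"), matrix.assays)
        export_network(g, "edgelist_tsv", base.with_suffix(".tsv"))
    export_network(consensus, "graphml", outdir / "networks" / "consensus.graphml", matrix.assays)
    export_network(consensus, "edgelist_tsv", outdir / "networks" / "consensus.tsv")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "criterion": config.criterion.to_dict(),
        "min_pairs": config.min_pairs,
        "min_detect_fraction": config.min_detect_fraction,
        "null_reps": config.null_reps,
        "n_samples": matrix.n_samples,
        "n_assays": matrix.n_assays,
        "n_cell_networks": len(cell_networks),
        "n_intersection_networks": len(timepoint_networks),
        "n_consensus_networks": 1,
        "consensus_nodes": consensus.number_of_nodes(),
        "consensus_edges": consensus.number_of_edges(),
        "cell_edge_counts": {
            f"{loc}_t{tp}": g.number_of_edges() for (loc, tp), g in sorted(cell_networks.items(), key=lambda kv: str(kv[0]))
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        matrix=matrix,
        truth=truth,
        cell_networks=cell_networks,
        cell_correlations=cell_correlations,
        timepoint_networks=timepoint_networks,
        consensus=consensus,
        stats_table=stats_frame,
        keystones=keystones,
        manifest=manifest,
    )
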