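"""Domain types and I/O for HT-qPCR functional-gene abundance data.

The quantification chain modelled here is the standard one for
high-throughput qPCR arrays: cycle-threshold (Ct) values are converted to
copies per reaction through a per-assay standard curve (linear regression of
Ct on log10 copies), scaled to copies per gram of dry soil, and analysed on
the log10 scale.  Non-detects (blank wells, Ct above the limit of detection)
are *masked*, never zero-filled: downstream inference is rank-based and
zero-filling would fabricate ties.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Pathway classes recognised for assay records.
PATHWAYS = frozenset(
    {"nitrification", "denitrification", "fixation", "dnra", "anammox", "other"}
)

#: Plant growth stages at sampling.
GROWTH_STAGES = frozenset({"anthesis", "regrowth"})

SAMPLE_META_COLUMNS = ("sample_id", "location", "timepoint", "season", "growth_stage")
ASSAY_META_COLUMNS = ("assay_id", "gene_symbol", "pathway", "taxon_group", "redundancy_group")


@dataclass(frozen=True)
class AssayRecord:
    """One qPCR primer pair targeting an N-cycle functional gene."""

    assay_id: str
    gene_symbol: str
    pathway: str
    taxon_group: str = ""
    redundancy_group: str | None = None

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise ValueError(
                f"unknown pathway {self.pathway!r} for assay {self.assay_id!r}; "
                f"expected one of {sorted(PATHWAYS)}"
            )


@dataclass(frozen=True)
class SampleRecord:
    """One soil sample with its grouping metadata.

    ``(location, timepoint)`` defines the grouping cell used for network
    construction.
    """

    sample_id: str
    location: str
    timepoint: int
    season: str = ""
    growth_stage: str = ""
    block: str | None = None

    def __post_init__(self) -> None:
        if self.growth_stage and self.growth_stage not in GROWTH_STAGES:
            raise ValueError(
                f"unknown growth stage {self.growth_stage!r} for sample {self.sample_id!r}"
            )


@dataclass(frozen=True)
class StandardCurve:
    """Linear standard curve Ct = slope * log10(copies) + intercept.

    slope is Ct per log10 copies and must be negative (more template, earlier
    threshold); intercept is the Ct of a single-copy reaction.  ``lod_ct``,
    when set, marks reactions at or above it as non-detects.
    """

    slope: float
    intercept: float
    lod_ct: float | None = None

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("standard-curve slope must be nonzero")
        if self.slope > 0:
            raise ValueError(f"standard-curve slope must be negative, got {self.slope}")


def ct_to_copies_per_g(
    ct: float,
    curve: StandardCurve,
    elution_volume: float,
    template_volume: float,
    dilution_factor: float = 1.0,
    soil_mass: float = 1.0,
) -> float:
    """Convert a Ct value to gene copies per gram of soil.

    copies/reaction = 10**((ct - intercept) / slope); the per-gram value
    scales by the fraction of the DNA elution loaded in the reaction, the
    dilution factor and the extracted soil mass.  Returns ``nan`` (non-detect)
    when ``ct >= curve.lod_ct``.
    """
    if ct < 0:
        raise ValueError(f"negative Ct value: {ct}")
    if soil_mass <= 0:
        raise ValueError(f"soil mass must be positive, got {soil_mass}")
    if template_volume <= 0:
        raise ValueError(f"template volume must be positive, got {template_volume}")
    if dilution_factor < 1:
        raise ValueError(f"dilution factor must be >= 1, got {dilution_factor}")
    if curve.lod_ct is not None and ct >= curve.lod_ct:
        return math.nan
    copies_per_reaction = 10.0 ** ((ct - curve.intercept) / curve.slope)
    return copies_per_reaction * (elution_volume / template_volume) * dilution_factor / soil_mass


@dataclass
class AbundanceMatrix:
    """Samples x assays abundance matrix with metadata joins.

    ``values`` is a samples x assays float DataFrame; masked cells
    (non-detects / missing wells) are ``NaN``.  ``samples`` and ``assays`` are
    metadata tables indexed by sample_id / assay_id in matrix order.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    assays: pd.DataFrame
    scale: str = "log10_copies_per_g"

    def __post_init__(self) -> None:
        if self.scale not in ("log10_copies_per_g", "copies_per_g"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicated sample ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicated assay ids: {dups}")
        if not self.values.index.equals(self.samples.index):
            raise ValueError("sample metadata index does not match matrix rows")
        if not self.values.columns.equals(self.assays.index):
            raise ValueError("assay metadata index does not match matrix columns")
        unmasked = self.values.to_numpy(dtype=float)
        if np.isinf(unmasked).any():
            raise ValueError("abundance values must be finite or NaN (masked)")
        # normalize axis names so round trips compare clean
        self.values.index.name = "sample_id"
        self.values.columns.name = "assay_id"
        self.samples.index.name = "sample_id"
        self.assays.index.name = "assay_id"

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the cell is missing/non-detect."""
        return self.values.isna()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_assays(self) -> int:
        return self.values.shape[1]

    def detection_fraction(self) -> pd.Series:
        """Per-assay fraction of unmasked cells."""
        return 1.0 - self.mask.mean(axis=0)

    def iter_cells(
        self, by: Sequence[str] = ("location", "timepoint")
    ) -> Iterator[tuple[tuple, "AbundanceMatrix"]]:
        """Yield ``(key, submatrix)`` per grouping cell, in sorted key order."""
        grouped = self.samples.groupby(list(by), sort=True)
        for key, meta in grouped:
            sub = AbundanceMatrix(
                values=self.values.loc[meta.index],
                samples=meta,
                assays=self.assays,
                scale=self.scale,
            )
            yield key, sub

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        out = self.values.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep=sep)

    def to_copies_per_g(self) -> "AbundanceMatrix":
        """Return the matrix on the raw copies-per-gram scale."""
        if self.scale == "copies_per_g":
            return self
        return AbundanceMatrix(10.0 ** self.values, self.samples, self.assays, "copies_per_g")

    def to_log10(self) -> "AbundanceMatrix":
        if self.scale == "log10_copies_per_g":
            return self
        return AbundanceMatrix(
            np.log10(self.values), self.samples, self.assays, "log10_copies_per_g"
        )


def _read_table(path: str | Path, fmt: str | None) -> pd.DataFrame:
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    if fmt not in ("csv", "tsv"):
        raise ValueError(f"unknown table format {fmt!r}")
    return pd.read_csv(path, sep="\t" if fmt == "tsv" else ",", dtype={0: str})


def read_abundance_table(
    path: str | Path,
    sample_meta: str | Path,
    assay_meta: str | Path,
    fmt: str | None = None,
    scale: str = "log10_copies_per_g",
) -> AbundanceMatrix:
    """Read a wide abundance table plus its two metadata tables.

    The abundance table's first column must be ``sample_id``; remaining
    columns are assay ids.  Every id in the matrix must appear in the
    corresponding metadata table.  Blank/NA cells become masked entries;
    non-numeric cells raise with their position.
    """
    raw = _read_table(path, fmt)
    if raw.columns[0] != "sample_id":
        raise ValueError(
            f"first column of {path} must be 'sample_id', found {raw.columns[0]!r}"
        )
    raw = raw.set_index("sample_id")
    values = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].astype(str).str.strip() != "")
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"non-numeric cell at sample {row!r}, assay {col!r}: {raw.loc[row, col]!r}"
            )
        values[col] = converted

    smeta = _read_table(sample_meta, None)
    ameta = _read_table(assay_meta, None)
    for required, frame, name in (
        (SAMPLE_META_COLUMNS, smeta, "sample metadata"),
        (ASSAY_META_COLUMNS[:4], ameta, "assay metadata"),
    ):
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"{name} is missing required columns: {missing}")
    smeta = smeta.set_index("sample_id")
    ameta = ameta.set_index("assay_id")

    unknown_samples = values.index.difference(smeta.index)
    if len(unknown_samples):
        raise ValueError(f"sample ids absent from sample metadata: {list(unknown_samples)}")
    unknown_assays = values.columns.difference(ameta.index)
    if len(unknown_assays):
        raise ValueError(f"assay ids absent from assay metadata: {list(unknown_assays)}")

    bad_pathways = set(ameta["pathway"]) - PATHWAYS
    if bad_pathways:
        raise ValueError(f"unknown pathway values in assay metadata: {sorted(bad_pathways)}")

    return AbundanceMatrix(
        values=values,
        samples=smeta.loc[values.index],
        assays=ameta.loc[values.columns],
        scale=scale,
    )


def write_abundance_table(
    matrix: AbundanceMatrix,
    path: str | Path,
    sample_meta: str | Path,
    assay_meta: str | Path,
    fmt: str = "csv",
) -> None:
    """Write the matrix and both metadata tables in the formats read back by
    :func:`read_abundance_table` (round-trip exact)."""
    sep = "\t" if fmt == "tsv" else ","
    matrix.to_csv(path, sep=sep)
    smeta = matrix.samples.reset_index()
    smeta.to_csv(sample_meta, index=False)
    ameta = matrix.assays.reset_index()
    ameta.to_csv(assay_meta, index=False)


def filter_assays(
    matrix: AbundanceMatrix,
    min_detect_fraction: float = 0.5,
    drop_failed_curves: bool = True,
) -> AbundanceMatrix:
    """Data-cleaning filter: retain assays detected in at least
    ``min_detect_fraction`` of samples.

    When ``drop_failed_curves`` is set and the assay metadata carries a
    boolean ``standard_curve_ok`` column, assays flagged False are removed as
    well.  Idempotent at a fixed threshold; the sample index is unchanged.
    """
    if not 0.0 <= min_detect_fraction <= 1.0:
        raise ValueError(f"min_detect_fraction must be in [0, 1], got {min_detect_fraction}")
    keep = matrix.detection_fraction() >= min_detect_fraction
    if drop_failed_curves and "standard_curve_ok" in matrix.assays.columns:
        ok = matrix.assays["standard_curve_ok"].astype(bool)
        keep &= ok
    dropped = [a for a, k in keep.items() if not k]
    if dropped:
        logger.info("filter_assays dropped %d assays: %s", len(dropped), dropped)
    cols = [a for a in matrix.values.columns if keep[a]]
    return AbundanceMatrix(
        values=matrix.values[cols],
        samples=matrix.samples,
        assays=matrix.assays.loc[cols],
        scale=matrix.scale,
    )
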