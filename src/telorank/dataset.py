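"""Cross-species gene position tables.

The central data structure is a gene × species matrix of *telomeric
distances*: the base-pair distance from a gene to the nearer end of its
chromosome's assembled sequence. Telomeres themselves are not annotated in
genome assemblies, so the assembly boundaries stand in for them. Input is a
long-format TSV with one row per ortholog (a human gene's counterpart in one
species); multiple orthologs of the same gene in the same species are
collapsed to their median distance.

Two inclusion filters mirror common ortholog-table curation: genes present in
too few species are dropped first, then species covering too few of the
remaining genes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OrthologPosition",
    "FilterThresholds",
    "PositionDataset",
    "DatasetError",
    "InvalidRecordError",
    "FormatError",
    "EmptyDatasetError",
    "telomeric_distance",
    "collapse_orthologs",
    "apply_filters",
    "load_dataset",
    "export_matrix",
    "load_matrix",
]

REQUIRED_COLUMNS = ("gene_id", "species_id", "chromosome_id", "start", "end", "chrom_end")
COORDINATE_COLUMNS = ("start", "end", "chrom_start", "chrom_end")


class DatasetError(ValueError):
    """Base class for dataset construction errors."""


class InvalidRecordError(DatasetError):
    """A row violates the coordinate-order invariants."""


class FormatError(DatasetError):
    """The input table is malformed (missing column, unparsable value)."""


class EmptyDatasetError(DatasetError):
    """Filtering removed every gene or every species."""


@dataclass(frozen=True)
class OrthologPosition:
    """One ortholog's chromosomal coordinates in one species.

    Coordinates are 1-based and inclusive (Ensembl convention).
    ``chrom_start``/``chrom_end`` delimit the assembled sequence; with
    ``chrom_start == 1``, ``chrom_end`` is the chromosome length.
    """

    gene_id: str
    species_id: str
    chromosome_id: str
    start: int
    end: int
    chrom_end: int
    chrom_start: int = 1

    def __post_init__(self) -> None:
        coords = (self.chrom_start, self.start, self.end, self.chrom_end)
        if any(int(c) != c or c < 1 for c in coords):
            raise InvalidRecordError(
                f"coordinates must be positive integers for {self.gene_id}/{self.species_id}: {coords}"
            )
        if not (self.chrom_start <= self.start <= self.end <= self.chrom_end):
            raise InvalidRecordError(
                f"coordinate order violated for {self.gene_id}/{self.species_id}: "
                f"need chrom_start <= start <= end <= chrom_end, got {coords}"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class FilterThresholds:
    """Inclusion thresholds for genes and species.

    A gene is kept if it has orthologs in at least ``min_species_fraction`` of
    the species (counted before any species is dropped); afterwards a species
    is kept if it has orthologs for at least ``min_gene_fraction`` of the
    remaining genes.
    """

    min_species_fraction: float = 0.25
    min_gene_fraction: float = 0.50

    def __post_init__(self) -> None:
        for name in ("min_species_fraction", "min_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class PositionDataset:
    """Filtered gene × species telomeric-distance matrix.

    ``distance`` has genes as rows and species as columns (both sorted
    lexicographically), NaN marking absent orthologs. ``positions`` keeps one
    representative chromosomal location per present (gene, species) pair —
    needed by scores that measure physical distance between genes.
    """

    distance: pd.DataFrame
    positions: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "species_id", "chromosome_id", "midpoint", "distance"]))
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.distance.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and finite.min() < 0:
            raise DatasetError("telomeric distances must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.distance.index)

    @property
    def species(self) -> list[str]:
        return list(self.distance.columns)

    def gene_distances(self, gene_id: str) -> np.ndarray:
        """Present telomeric distances of one gene across species."""
        row = self.distance.loc[gene_id]
        return row.dropna().to_numpy(dtype=float)

    def presence_fraction(self, gene_id: str) -> float:
        return float(self.distance.loc[gene_id].notna().mean())


def telomeric_distance(p: OrthologPosition) -> int:
    """Distance (bp) from the gene to the nearer assembly end.

    ``min(start - chrom_start, chrom_end - end)``; zero when the gene abuts
    either end of the assembled sequence.
    """
    return min(p.start - p.chrom_start, p.chrom_end - p.end)


def collapse_orthologs(records: list[OrthologPosition]) -> float:
    """Median telomeric distance over several orthologs of one (gene, species).

    An even count yields the mean of the two central values. Robust to a
    single mis-annotated duplicate and deterministic.
    """
    if not records:
        raise ValueError("collapse_orthologs needs at least one record")
    key = {(r.gene_id, r.species_id) for r in records}
    if len(key) != 1:
        raise ValueError(f"records span multiple (gene, species) pairs: {sorted(key)}")
    return float(np.median([telomeric_distance(r) for r in records]))


def apply_filters(
    distance: pd.DataFrame,
    thresholds: FilterThresholds = FilterThresholds(),
    positions: pd.DataFrame | None = None,
) -> PositionDataset:
    """Apply gene and species inclusion filters, in that order, once.

    Gene presence is judged against the full, pre-filter species count;
    species coverage against the gene set remaining after the gene filter.
    The two passes are deliberately not iterated to a fixed point, so the
    order is part of the contract.
    """
    if distance.empty:
        raise EmptyDatasetError("input table has no genes or no species")
    n_genes_before, n_species_before = distance.shape

    present = distance.notna()
    keep_genes = present.sum(axis=1) >= thresholds.min_species_fraction * n_species_before
    filtered = distance.loc[keep_genes]
    if filtered.empty:
        raise EmptyDatasetError("gene filter removed every gene")

    keep_species = filtered.notna().sum(axis=0) >= thresholds.min_gene_fraction * len(filtered)
    filtered = filtered.loc[:, keep_species]
    if filtered.shape[1] == 0:
        raise EmptyDatasetError("species filter removed every species")

    filtered = filtered.sort_index().sort_index(axis=1)
    if positions is not None and not positions.empty:
        positions = positions[
            positions["gene_id"].isin(filtered.index)
            & positions["species_id"].isin(filtered.columns)
        ].reset_index(drop=True)
    else:
        positions = None

    provenance = {
        "thresholds": {
            "min_species_fraction": thresholds.min_species_fraction,
            "min_gene_fraction": thresholds.min_gene_fraction,
        },
        "n_genes_before": int(n_genes_before),
        "n_species_before": int(n_species_before),
        "n_genes_after": int(filtered.shape[0]),
        "n_species_after": int(filtered.shape[1]),
    }
    ds = PositionDataset(
        distance=filtered,
        positions=positions if positions is not None else pd.DataFrame(
            columns=["gene_id", "species_id", "chromosome_id", "midpoint", "distance"]),
        provenance=provenance,
    )
    _assert_invariants(ds)
    return ds


def _assert_invariants(ds: PositionDataset) -> None:
    vals = ds.distance.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    assert finite.size == 0 or finite.min() >= 0, "negative telomeric distance"
    assert not ds.distance.notna().sum(axis=1).eq(0).any(), "gene with no species survived filtering"


def load_dataset(
    path,
    thresholds: FilterThresholds = FilterThresholds(),
) -> PositionDataset:
    """Load a long-format ortholog position TSV and build the filtered dataset.

    Required header columns: gene_id, species_id, chromosome_id, start, end,
    chrom_end; chrom_start is optional (defaults to 1). Gzip input is handled
    transparently. Rows for the same (gene, species) are collapsed to their
    median distance; the row whose distance realises the (lower) median keeps
    its chromosomal position as the representative for physical-distance
    scores.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if "chrom_start" not in raw.columns:
        raw["chrom_start"] = "1"
    if raw.empty:
        raise EmptyDatasetError("input table has no rows")

    for col in COORDINATE_COLUMNS:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() | (converted != np.floor(converted))
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise FormatError(f"non-integer value {raw[col][bad.idxmax()]!r} in column {col}, line {line}")
        raw[col] = converted.astype(np.int64)

    order_ok = (
        (raw["chrom_start"] <= raw["start"])
        & (raw["start"] <= raw["end"])
        & (raw["end"] <= raw["chrom_end"])
        & (raw["chrom_start"] >= 1)
    )
    if not order_ok.all():
        i = int((~order_ok).idxmax())
        r = raw.loc[i]
        raise InvalidRecordError(
            f"coordinate order violated at line {i + 2} "
            f"(gene {r['gene_id']}, species {r['species_id']})"
        )

    raw["distance"] = np.minimum(raw["start"] - raw["chrom_start"], raw["chrom_end"] - raw["end"]).astype(float)
    raw["midpoint"] = (raw["start"] + raw["end"]) / 2.0

    # Collapse duplicates: median distance; representative row = lower median
    # by distance (ties by chromosome then midpoint) so positions stay real.
    raw = raw.sort_values(
        ["gene_id", "species_id", "distance", "chromosome_id", "midpoint"],
        kind="mergesort",
    ).reset_index(drop=True)
    grouped = raw.groupby(["gene_id", "species_id"], sort=True)
    collapsed = grouped["distance"].median().rename("distance").reset_index()
    sizes = grouped["distance"].transform("size")
    pick = grouped.cumcount() == (sizes - 1) // 2
    reps = raw.loc[pick, ["gene_id", "species_id", "chromosome_id", "midpoint"]].reset_index(drop=True)
    positions = reps.merge(collapsed, on=["gene_id", "species_id"], validate="one_to_one")

    matrix = collapsed.pivot(index="gene_id", columns="species_id", values="distance")
    matrix = matrix.sort_index().sort_index(axis=1)
    matrix.index.name = None
    matrix.columns.name = None
    return apply_filters(matrix, thresholds, positions=positions)


def export_matrix(ds: PositionDataset, path) -> None:
    """Write the filtered distance matrix as TSV (genes × species, empty = missing)."""
    out = ds.distance.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep="")


def load_matrix(path) -> pd.DataFrame:
    """Read a matrix TSV written by :func:`export_matrix`."""
    m = pd.read_csv(path, sep="\t", index_col="gene_id")
    m.index.name = None
    return m.astype(float)


def file_sha256(path) -> str:
    """Checksum helper used by run manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
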