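"""Synthetic cross-species gene-position datasets with planted signal.

The generator emulates the statistical structure of an ortholog position
export: a set of species with a handful of chromosomes each, human genes
with presence/absence structure across species, and two populations of
genes:

* **planted** genes keep a conserved telomeric distance — per species the
  distance is drawn Normal(planted_distance, jitter²) truncated at zero and
  the gene is placed at that distance from a uniformly chosen end (arm) of a
  uniformly chosen chromosome. Conservation is of telomeric *distance*, not
  of chromosome identity, which is exactly what the scores measure.
* **background** genes are placed uniformly on a random chromosome per
  species — the maximal-rearrangement null, under which no positional signal
  survives across species.

Ortholog dropout is i.i.d. per (gene, species). Everything is deterministic
given the seed, and the emitted TSV round-trips through
:func:`telorank.dataset.load_dataset`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import FilterThresholds, PositionDataset, load_dataset
from .ranking import (
    GeneSetReport,
    OptimizationConfig,
    OptimizationResult,
    Ranking,
    combine_scores,
    evaluate_gene_set,
    optimize_weights,
    rank_genes,
)
from .reference_free_scores import (
    ClusterConfig,
    KdeConfig,
    clustering_score_vector,
    distance_score,
)
from .reference_scores import (
    RandomForestConfig,
    ReferenceSet,
    adjacency_score,
    correlation_score,
    random_forest_score,
)

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "generate_positions",
    "generate_dataset",
    "write_dataset",
    "RecoveryReport",
    "recovery_report",
    "compute_all_scores",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    Defaults describe the standard fixture: 20 species with 5 chromosomes of
    50–150 Mb, 500 genes of which 10 are planted at a 3 Mb telomeric distance
    (within the ~15 Mb window over which telomeres are thought to reach genes
    through chromatin loops) with 100 kb jitter, and 20% ortholog dropout.
    """

    n_species: int = 20
    n_genes: int = 500
    n_chromosomes: int = 5
    chromosome_length_range: tuple[int, int] = (50_000_000, 150_000_000)
    n_planted: int = 10
    planted_distance: int = 3_000_000
    planted_jitter_sd: int = 100_000
    ortholog_dropout: float = 0.2
    gene_length_range: tuple[int, int] = (1_000, 100_000)
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 <= self.n_planted <= self.n_genes:
            raise ValueError("n_planted must be between 0 and n_genes")
        if not 0.0 <= self.ortholog_dropout <= 1.0:
            raise ValueError("ortholog_dropout must be a probability")
        min_len = self.chromosome_length_range[0]
        if self.planted_distance + 4 * self.planted_jitter_sd >= min_len / 2:
            raise ValueError(
                "planted_distance + 4·jitter_sd must stay below half the shortest chromosome"
            )
        if self.gene_length_range[0] < 1 or self.gene_length_range[1] >= min_len // 4:
            raise ValueError("gene_length_range infeasible for the chromosome lengths")

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def planted_ids(self) -> list[str]:
        return self.gene_ids()[: self.n_planted]

    def species_ids(self) -> list[str]:
        width = max(2, len(str(self.n_species)))
        return [f"S{i:0{width}d}" for i in range(1, self.n_species + 1)]


@dataclass
class PlantedTruth:
    """Which genes carry the planted signal, and their emitted distances."""

    planted_genes: list[str]
    distances: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({"planted_genes": self.planted_genes, "distances": self.distances}, indent=1)
        )

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        data = json.loads(Path(path).read_text())
        return cls(planted_genes=data["planted_genes"], distances=data["distances"])


def generate_positions(cfg: SyntheticConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Generate the long-format position table and the planted-gene truth.

    Returns a DataFrame with the canonical TSV columns (gene_id, species_id,
    chromosome_id, start, end, chrom_start, chrom_end) and a
    :class:`PlantedTruth` whose recorded distances match the emitted rows
    exactly (post-dropout).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_ids()
    species = cfg.species_ids()
    planted = set(cfg.planted_ids())

    lo_len, hi_len = cfg.chromosome_length_range
    chrom_lengths = {
        s: rng.integers(lo_len, hi_len + 1, size=cfg.n_chromosomes) for s in species
    }

    rows = []
    truth = PlantedTruth(planted_genes=sorted(planted))
    for gene in genes:
        for sp in species:
            if rng.random() < cfg.ortholog_dropout:
                continue
            lengths = chrom_lengths[sp]
            chrom = int(rng.integers(cfg.n_chromosomes))
            L = int(lengths[chrom])
            gene_len = int(rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1))
            if gene in planted:
                d = max(0, int(round(rng.normal(cfg.planted_distance, cfg.planted_jitter_sd))))
                if rng.random() < 0.5:  # p-arm
                    start = 1 + d
                    end = start + gene_len - 1
                else:  # q-arm
                    end = L - d
                    start = end - gene_len + 1
            else:
                start = int(rng.integers(1, L - gene_len + 2))
                end = start + gene_len - 1
            rows.append((gene, sp, f"chr{chrom + 1}", start, end, 1, L))
            if gene in planted:
                truth.distances.setdefault(gene, {})[sp] = float(min(start - 1, L - end))

    df = pd.DataFrame(
        rows,
        columns=["gene_id", "species_id", "chromosome_id", "start", "end", "chrom_start", "chrom_end"],
    )
    return df, truth


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write the long-format table as the canonical TSV."""
    df.to_csv(path, sep="\t", index=False)


def compute_all_scores(
    ds: PositionDataset,
    refs: ReferenceSet,
    kde_cfg: KdeConfig = KdeConfig(),
    cluster_cfg: ClusterConfig = ClusterConfig(),
    rf_cfg: RandomForestConfig = RandomForestConfig(),
):
    """All five method scores in canonical order.

    Order: distance, clustering, adjacency, correlation, random_forest.
    """
    return [
        distance_score(ds, kde_cfg),
        clustering_score_vector(ds, cluster_cfg),
        adjacency_score(ds, refs, kde_cfg),
        correlation_score(ds, refs),
        random_forest_score(ds, refs, rf_cfg),
    ]


@dataclass
class RecoveryReport:
    """Held-out planted genes' standing in the optimised combined ranking."""

    reference_genes: list[str]
    held_out_genes: list[str]
    held_out: GeneSetReport
    optimization: OptimizationResult
    ranking: Ranking


def recovery_report(
    ds: PositionDataset,
    truth: PlantedTruth,
    k_refs: int,
    kde_cfg: KdeConfig = KdeConfig(),
    cluster_cfg: ClusterConfig = ClusterConfig(),
    rf_cfg: RandomForestConfig = RandomForestConfig(),
    opt_cfg: OptimizationConfig = OptimizationConfig(),
) -> RecoveryReport:
    """Run the full pipeline with the first ``k_refs`` planted genes as
    references and evaluate the remaining planted genes.

    Mirrors a known-vs-suggested validation design: the references calibrate
    the reference-dependent scores and the combination weights; the held-out
    planted genes carry the same positional signal but contribute nothing to
    training or optimisation.
    """
    planted = [g for g in truth.planted_genes if g in set(ds.genes)]
    if not 0 < k_refs < len(planted):
        raise ValueError(f"k_refs must be in (0, {len(planted)}) for this dataset")
    ref_ids = planted[:k_refs]
    held_out = planted[k_refs:]
    refs = ReferenceSet(ref_ids)
    scores = compute_all_scores(ds, refs, kde_cfg, cluster_cfg, rf_cfg)
    result = optimize_weights(scores, refs, opt_cfg)
    ranking = rank_genes(combine_scores(scores, result.weights))
    report = evaluate_gene_set(ranking, held_out)
    return RecoveryReport(
        reference_genes=ref_ids,
        held_out_genes=held_out,
        held_out=report,
        optimization=result,
        ranking=ranking,
    )


def generate_dataset(
    cfg: SyntheticConfig,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[PositionDataset, PlantedTruth]:
    """Generate, round-trip through the TSV loader, and filter.

    Going through :func:`load_dataset` keeps the in-memory path identical to
    the file-based one.
    """
    import io

    df, truth = generate_positions(cfg)
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    ds = load_dataset(buf, thresholds)
    return ds, truth
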