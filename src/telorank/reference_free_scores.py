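"""Scores that need no reference gene set.

Two per-gene summaries of the cross-species telomeric-distance profile:

* **distance score** — the mode of a Gaussian kernel density estimate over a
  gene's telomeric distances across species. The mode is a robust "typical
  position"; after min–max normalisation over genes, genes whose orthologs sit
  far from the telomeres score highest.
* **clustering score** — how tightly the distances cluster. Complete-linkage
  agglomerative clustering in one dimension, tree cut so every cluster spans
  at most 1 Mb; the score is a decay-weighted sum of cluster-size proportions
  (largest cluster at full weight, each subsequent cluster halved), hence 1
  exactly when all orthologs keep the same telomeric distance to within 1 Mb.

The KDE follows the classic rule-of-thumb setup: bandwidth
0.9 · min(sd, IQR/1.34) · n^(−1/5), density evaluated on a 512-point grid
extended three bandwidths beyond the data range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .dataset import PositionDataset

__all__ = [
    "KdeConfig",
    "ClusterConfig",
    "ScoreVector",
    "minmax_normalize",
    "rule_of_thumb_bandwidth",
    "kde_mode",
    "distance_score",
    "cluster_1d",
    "clustering_score",
    "clustering_score_vector",
]


@dataclass(frozen=True)
class KdeConfig:
    """Kernel density estimation settings.

    grid_points: number of equally spaced evaluation points.
    grid_cut: how many bandwidths the grid extends beyond min/max of the data.
    """

    grid_points: int = 512
    grid_cut: float = 3.0

    def __post_init__(self) -> None:
        if self.grid_points < 2:
            raise ValueError("grid_points must be >= 2")
        if self.grid_cut < 0:
            raise ValueError("grid_cut must be >= 0")


@dataclass(frozen=True)
class ClusterConfig:
    """1-D clustering settings: maximum intra-cluster span (bp) and per-rank decay."""

    max_span: float = 1_000_000.0
    decay: float = 0.5

    def __post_init__(self) -> None:
        if self.max_span <= 0:
            raise ValueError("max_span must be positive")
        if not 0.0 < self.decay < 1.0:
            raise ValueError("decay must be in (0, 1)")


@dataclass
class ScoreVector:
    """Per-gene scores of one method.

    ``scores`` are min–max normalised to [0, 1] over genes (all-equal raw
    values map to a constant 0.5 so weighted averages stay defined); ``raw``
    keeps the pre-normalisation values. ``meta`` carries method-specific audit
    information (e.g. model provenance).
    """

    method_id: str
    scores: pd.Series
    raw: pd.Series
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = self.scores.to_numpy(dtype=float)
        if s.size and (s.min() < -1e-12 or s.max() > 1 + 1e-12):
            raise ValueError(f"normalized scores outside [0, 1] for method {self.method_id}")

    def to_tsv(self, path) -> None:
        out = self.scores.rename("score").to_frame()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


def minmax_normalize(raw: pd.Series, invert: bool = False) -> pd.Series:
    """Min–max normalise to [0, 1]; degenerate all-equal input maps to 0.5."""
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        return pd.Series(0.5, index=raw.index)
    s = (raw - lo) / (hi - lo)
    return 1.0 - s if invert else s


def rule_of_thumb_bandwidth(values: np.ndarray) -> float:
    """Silverman-style rule-of-thumb bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5).

    Falls back to sd, then |x₁|, then 1 when the preferred spread measure is
    zero, so a usable positive bandwidth is returned for any non-constant
    sample.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    lo = min(sd, (q75 - q25) / 1.34)
    if lo == 0.0:
        lo = sd or abs(float(x[0])) or 1.0
    return 0.9 * lo * n ** (-0.2)


def kde_mode(distances: Sequence[float], cfg: KdeConfig = KdeConfig()) -> float:
    """Location of maximum Gaussian-KDE density over a 1-D sample.

    Evaluated on ``cfg.grid_points`` equally spaced points spanning
    [min − grid_cut·h, max + grid_cut·h]. Ties go to the smallest location
    (the grid is ascending and the first maximum wins). A constant sample has
    no defined bandwidth; its common value is returned directly, matching the
    h → 0 limit of the estimator.
    """
    x = np.asarray(list(distances), dtype=float)
    if x.size == 0:
        raise ValueError("kde_mode needs at least one value")
    if x.size == 1 or np.all(x == x[0]):
        return float(x[0])
    h = rule_of_thumb_bandwidth(x)
    grid = np.linspace(x.min() - cfg.grid_cut * h, x.max() + cfg.grid_cut * h, cfg.grid_points)
    z = (grid[:, None] - x[None, :]) / h
    density = np.exp(-0.5 * z * z).sum(axis=1)  # unnormalised; argmax unaffected
    return float(grid[int(np.argmax(density))])


def distance_score(ds: PositionDataset, cfg: KdeConfig = KdeConfig()) -> ScoreVector:
    """Per-gene KDE-mode of telomeric distances, min–max normalised over genes.

    High scores mean the gene's typical ortholog position is far from the
    telomeres; low scores mean consistently telomere-proximal.
    """
    raw = {}
    for gene in ds.genes:
        values = ds.gene_distances(gene)
        assert values.size > 0, f"gene {gene} has no present entries post-filter"
        raw[gene] = kde_mode(values, cfg)
    raw_series = pd.Series(raw, dtype=float).reindex(ds.genes)
    return ScoreVector("distance", minmax_normalize(raw_series), raw_series)


def cluster_1d(distances: Sequence[float], cfg: ClusterConfig = ClusterConfig()) -> list[list[float]]:
    """Complete-linkage clustering of 1-D values, tree cut at ``max_span``.

    Complete linkage makes the cut height a literal bound on each cluster's
    internal span (max pairwise absolute difference ≤ max_span). Clusters are
    returned sorted by size descending, ties by smallest member ascending.
    """
    x = np.asarray(list(distances), dtype=float)
    if x.size == 0:
        raise ValueError("cluster_1d needs at least one value")
    if x.size == 1:
        return [[float(x[0])]]
    Z = linkage(x[:, None], method="complete")
    labels = fcluster(Z, t=cfg.max_span, criterion="distance")
    clusters: dict[int, list[float]] = {}
    for value, label in zip(x, labels):
        clusters.setdefault(int(label), []).append(float(value))
    return sorted(clusters.values(), key=lambda c: (-len(c), min(c)))


def clustering_score(
    clusters: Sequence[Sequence[float]],
    n_orthologs: int,
    cfg: ClusterConfig = ClusterConfig(),
) -> float:
    """Decay-weighted sum of cluster-size proportions.

    score = Σ_i p_i · decay^(i−1), p_i = |cluster_i| / n_orthologs, clusters
    ordered largest first. Equals 1 iff a single cluster holds everything.
    """
    sizes = [len(c) for c in clusters]
    if sum(sizes) != n_orthologs:
        raise ValueError(f"cluster sizes {sizes} do not partition {n_orthologs} orthologs")
    return float(sum((s / n_orthologs) * cfg.decay**i for i, s in enumerate(sizes)))


def clustering_score_vector(ds: PositionDataset, cfg: ClusterConfig = ClusterConfig()) -> ScoreVector:
    """Clustering score per gene over its present telomeric distances."""
    raw = {}
    for gene in ds.genes:
        values = ds.gene_distances(gene)
        clusters = cluster_1d(values, cfg)
        raw[gene] = clustering_score(clusters, values.size, cfg)
    raw_series = pd.Series(raw, dtype=float).reindex(ds.genes)
    return ScoreVector("clustering", minmax_normalize(raw_series), raw_series)
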