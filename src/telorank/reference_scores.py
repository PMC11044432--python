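"""Scores calibrated on a user-supplied reference gene set.

The reference genes are assumed to share a positional mechanism (for the
telomere position effect over long distances, the six 3D-FISH-verified genes
C1S, DSP, ISG15, SORBS2, TERT and PPP2R2C). Three scores measure different
flavours of "positioned like the references":

* **adjacency** — the physical distance to the nearest reference-gene
  ortholog on the same chromosome replaces the distance to the telomere; the
  KDE-mode of those distances is inverted after normalisation, so genes that
  typically sit next to the references score high.
* **correlation** — median Spearman rank correlation, over references, of
  the gene's telomeric-distance profile against each reference's profile
  across the species both are present in.
* **random forest** — one regression forest per reference gene, trained on
  every gene except that reference with 0/1 labels marking the remaining
  references (class-balancing case weights). A reference gene is scored only
  by the model that never saw it; all other genes get the mean prediction of
  all models.

Every score excludes a reference gene from the computation of its own value,
so a reference's score reflects only the *other* references.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestRegressor

from .dataset import PositionDataset
from .reference_free_scores import KdeConfig, ScoreVector, kde_mode, minmax_normalize

__all__ = [
    "ReferenceSet",
    "RandomForestConfig",
    "adjacency_score",
    "correlation_score",
    "random_forest_score",
    "feature_matrix",
]

BP_PER_MB = 1_000_000.0


@dataclass(frozen=True)
class ReferenceSet:
    """Reference gene ids, ordered deterministically."""

    gene_ids: frozenset[str]

    def __init__(self, gene_ids: Iterable[str]) -> None:
        object.__setattr__(self, "gene_ids", frozenset(gene_ids))
        if not self.gene_ids:
            raise ValueError("reference set must not be empty")

    @property
    def ordered(self) -> list[str]:
        return sorted(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids

    def __len__(self) -> int:
        return len(self.gene_ids)

    def validate_against(self, ds: PositionDataset) -> None:
        missing = self.gene_ids - set(ds.genes)
        if missing:
            raise ValueError(f"reference gene(s) not in dataset: {', '.join(sorted(missing))}")


@dataclass(frozen=True)
class RandomForestConfig:
    """Forest hyperparameters; the seed is fixed and recorded for reproducibility."""

    n_trees: int = 500
    features_per_split: int | None = None  # None -> floor(sqrt(#features))
    seed: int = 0
    missing_sentinel: float = -1.0
    keep_predictions: bool = False  # retain the per-model prediction table for audit

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def adjacency_score(
    ds: PositionDataset,
    refs: ReferenceSet,
    cfg: KdeConfig = KdeConfig(),
) -> ScoreVector:
    """Typical physical distance to the nearest reference ortholog.

    Per gene and species, the bp distance from the gene's midpoint to the
    nearest reference-gene ortholog midpoint on the same chromosome in that
    species; species with no same-chromosome reference ortholog contribute
    nothing. The raw value is the KDE-mode of these per-species distances;
    normalisation is inverted (1 − min–max) so proximity scores high. A gene
    with no usable species is recorded in ``meta['no_usable_species']`` and
    treated as maximally distant (raw = global max) before inversion.
    """
    refs.validate_against(ds)
    pos = ds.positions
    if pos.empty:
        raise ValueError("dataset carries no chromosomal positions; adjacency needs them")
    ref_pos = pos[pos["gene_id"].isin(refs.gene_ids)]
    ref_pos = ref_pos.rename(columns={"gene_id": "ref_id", "midpoint": "ref_midpoint"})
    merged = pos.merge(
        ref_pos[["ref_id", "species_id", "chromosome_id", "ref_midpoint"]],
        on=["species_id", "chromosome_id"],
        how="inner",
    )
    merged = merged[merged["gene_id"] != merged["ref_id"]]
    merged["adj"] = (merged["midpoint"] - merged["ref_midpoint"]).abs()
    nearest = merged.groupby(["gene_id", "species_id"], sort=True)["adj"].min()

    raw = {}
    missing = []
    for gene in ds.genes:
        try:
            dists = nearest.xs(gene, level="gene_id").to_numpy(dtype=float)
        except KeyError:
            dists = np.empty(0)
        if dists.size:
            raw[gene] = kde_mode(dists, cfg)
        else:
            missing.append(gene)
    fill = max(raw.values()) if raw else 0.0
    for gene in missing:
        raw[gene] = fill
    raw_series = pd.Series(raw, dtype=float).reindex(ds.genes)
    return ScoreVector(
        "adjacency",
        minmax_normalize(raw_series, invert=True),
        raw_series,
        meta={"no_usable_species": missing},
    )


def correlation_score(
    ds: PositionDataset,
    refs: ReferenceSet,
    min_shared_species: int = 3,
) -> ScoreVector:
    """Median Spearman correlation with the reference distance profiles.

    Each gene is compared with every reference other than itself over the
    species where both have orthologs; pairs sharing fewer than
    ``min_shared_species`` species (or with a constant profile, where the
    rank correlation is undefined) are skipped. Genes with no usable
    comparison get raw 0.
    """
    refs.validate_against(ds)
    D = ds.distance
    ref_rows = {r: D.loc[r] for r in refs.ordered}
    raw = {}
    for gene in ds.genes:
        g_row = D.loc[gene]
        cors = []
        for r, r_row in ref_rows.items():
            if r == gene:
                continue
            both = g_row.notna() & r_row.notna()
            if int(both.sum()) < min_shared_species:
                continue
            rho = spearmanr(g_row[both], r_row[both]).statistic
            if np.isfinite(rho):
                cors.append(float(rho))
        raw[gene] = float(np.median(cors)) if cors else 0.0
    raw_series = pd.Series(raw, dtype=float).reindex(ds.genes)
    return ScoreVector("correlation", minmax_normalize(raw_series), raw_series)


def feature_matrix(ds: PositionDataset, cfg: RandomForestConfig = RandomForestConfig()) -> pd.DataFrame:
    """Per-gene features: per-species telomeric distance (Mb, missing →
    sentinel) plus the fraction of species with an ortholog."""
    X = (ds.distance / BP_PER_MB).fillna(cfg.missing_sentinel)
    X["__presence_fraction__"] = ds.distance.notna().mean(axis=1)
    return X


def random_forest_score(
    ds: PositionDataset,
    refs: ReferenceSet,
    cfg: RandomForestConfig = RandomForestConfig(),
) -> ScoreVector:
    """Leave-one-reference-out random-forest score.

    One regression forest per reference gene r, trained on all genes except
    r: labels are 1 for the remaining references and 0 otherwise, with case
    weights equalising total positive and negative weight. r is scored only
    by its own held-out model; every non-reference gene gets the mean of all
    models' predictions. Predictions lie in [0, 1] by construction (leaf
    values are averages of 0/1 labels). ``meta['models']`` records which
    model(s) scored which gene.
    """
    refs.validate_against(ds)
    if len(refs) < 2:
        raise ValueError("random forest scoring needs at least 2 reference genes")
    X = feature_matrix(ds, cfg)
    genes = np.array(ds.genes)
    max_features = cfg.features_per_split or max(1, int(np.sqrt(X.shape[1])))
    child_seeds = np.random.SeedSequence(cfg.seed).generate_state(len(refs)) % (2**31)

    preds = pd.DataFrame(index=ds.genes, columns=refs.ordered, dtype=float)
    for r, child_seed in zip(refs.ordered, child_seeds):
        train = genes != r
        y = np.isin(genes, [g for g in refs.ordered if g != r]).astype(float)[train]
        n_pos, n_neg = int(y.sum()), int((1 - y).sum())
        if n_pos == 0 or n_neg == 0:
            raise ValueError("training set needs both reference and background genes")
        weights = np.where(y == 1.0, 0.5 / n_pos, 0.5 / n_neg)
        forest = RandomForestRegressor(
            n_estimators=cfg.n_trees,
            max_features=max_features,
            random_state=int(child_seed),
            n_jobs=1,
        )
        forest.fit(X.loc[train].to_numpy(), y, sample_weight=weights)
        preds[r] = forest.predict(X.to_numpy())

    raw = {}
    provenance = {}
    for gene in ds.genes:
        if gene in refs:
            raw[gene] = float(preds.at[gene, gene])
            provenance[gene] = [gene]
        else:
            raw[gene] = float(preds.loc[gene].mean())
            provenance[gene] = refs.ordered
    raw_series = pd.Series(raw, dtype=float).reindex(ds.genes)
    meta = {"models": provenance, "seed": cfg.seed}
    if cfg.keep_predictions:
        meta["model_predictions"] = preds
    return ScoreVector("random_forest", minmax_normalize(raw_series), raw_series, meta=meta)
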