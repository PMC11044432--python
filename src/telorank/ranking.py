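"""Combined ranking: weighted score averaging and rank-based weight fitting.

The combined score of gene g is the signed weighted average

    s(g) = Σ_m w_m · s_m(g) / Σ_m |w_m|

over the normalised method scores s_m ∈ [0, 1]; weights may be negative, so
a method can count against a gene. Weights are fitted by minimising the mean
rank of the reference genes with a derivative-free simplex search. The
objective is piecewise constant in w (ranks only change when two combined
scores cross), so the search is multi-start — from the all-ones vector, every
unit vector, and their negations — with plateau-escaping restarts; the
returned optimum is never worse than any start, hence never worse than any
single method alone.

Percentiles are reported as 100 · (1 − rank/n), rank 1 being the best gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import mannwhitneyu

from .reference_free_scores import ScoreVector
from .reference_scores import ReferenceSet

__all__ = [
    "WeightVector",
    "Ranking",
    "OptimizationConfig",
    "OptimizationResult",
    "LooReport",
    "GeneSetReport",
    "percentile_of_rank",
    "combine_scores",
    "rank_genes",
    "optimize_weights",
    "loo_validate",
    "evaluate_gene_set",
    "bucket_ranking",
    "export_buckets",
]


@dataclass(frozen=True)
class WeightVector:
    """Signed per-method weights."""

    methods: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.methods) != len(self.weights):
            raise ValueError("methods and weights must have equal length")
        if not any(w != 0.0 for w in self.weights):
            raise ValueError("weights must not all be zero")

    @property
    def report_normalized(self) -> tuple[float, ...]:
        """Weights divided by the largest absolute weight (max |w| becomes 1)."""
        scale = max(abs(w) for w in self.weights)
        return tuple(w / scale for w in self.weights)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.methods, self.weights))


@dataclass
class Ranking:
    """Per-gene combined score, rank (1 = best) and percentile."""

    table: pd.DataFrame  # index: gene_id; columns: combined_score, rank, percentile

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def genes_by_rank(self) -> list[str]:
        return list(self.table.sort_values("rank").index)

    def rank_of(self, gene_id: str) -> int:
        return int(self.table.at[gene_id, "rank"])

    def percentile_of(self, gene_id: str) -> float:
        return float(self.table.at[gene_id, "percentile"])

    def to_tsv(self, path, method_scores: Sequence[ScoreVector] = ()) -> None:
        out = self.table.copy()
        for sv in method_scores:
            out.insert(0, f"score_{sv.method_id}", sv.scores.reindex(out.index))
        out = out.sort_values("rank")
        out["percentile"] = out["percentile"].round(2)
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6g")


@dataclass(frozen=True)
class OptimizationConfig:
    """Simplex-search settings.

    Default starts are the all-ones vector, each unit vector, and their
    negations — weights are signed by design (a method can count against a
    gene), so the search must not be biased toward the positive orthant.
    After each Nelder–Mead run the search restarts from the incumbent with a
    fresh simplex at several step scales until no restart improves; the
    objective is piecewise constant, so a converged simplex is often merely
    stranded on a plateau.
    """

    starts: tuple[tuple[float, ...], ...] | None = None
    max_iterations: int = 2000
    simplex_step: float = 0.5
    restart_scales: tuple[float, ...] = (1.0, 0.25)
    max_restart_rounds: int = 4


@dataclass
class OptimizationResult:
    """Fitted weights plus objective provenance for the weights JSON."""

    weights: WeightVector
    objective: float  # mean rank of the reference genes at the optimum
    start_objectives: list[float] = field(default_factory=list)
    best_start_index: int = 0

    def to_json_dict(self) -> dict:
        return {
            "methods": list(self.weights.methods),
            "weights": list(self.weights.weights),
            "weights_normalized": list(self.weights.report_normalized),
            "objective_mean_rank": self.objective,
            "start_objectives": self.start_objectives,
            "best_start_index": self.best_start_index,
        }


@dataclass
class LooReport:
    """Leave-one-out validation of the weight optimisation."""

    mean_percentile: float
    per_gene_percentile: dict[str, float]


@dataclass
class GeneSetReport:
    """Percentile summary and rank-sum test for an arbitrary gene set."""

    n_set: int
    mean_percentile: float
    min_percentile: float
    max_percentile: float
    p_value: float

    def to_json_dict(self) -> dict:
        return self.__dict__.copy()


def percentile_of_rank(rank: int | np.ndarray, n: int) -> float | np.ndarray:
    """Percentile of a rank among n genes: 100 · (1 − rank/n)."""
    return 100.0 * (1.0 - np.asarray(rank) / n) if np.ndim(rank) else 100.0 * (1.0 - rank / n)


def _score_matrix(scores: Sequence[ScoreVector]) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    genes = list(scores[0].scores.index)
    for sv in scores[1:]:
        if list(sv.scores.index) != genes:
            raise ValueError("all score vectors must cover the same gene list in the same order")
    S = np.column_stack([sv.scores.to_numpy(dtype=float) for sv in scores])
    return S, np.array(genes), tuple(sv.method_id for sv in scores)


def combine_scores(scores: Sequence[ScoreVector], w: WeightVector) -> pd.Series:
    """Signed weighted average Σ w_m·s_m / Σ|w_m|, linear in each method score."""
    S, genes, methods = _score_matrix(scores)
    if methods != w.methods:
        raise ValueError(f"weight methods {w.methods} do not match scores {methods}")
    arr = np.asarray(w.weights, dtype=float)
    combined = S @ arr / np.abs(arr).sum()
    return pd.Series(combined, index=genes, name="combined_score")


def rank_genes(combined: pd.Series) -> Ranking:
    """Rank by descending combined score; ties broken by gene id (lexicographic)."""
    if combined.empty:
        raise ValueError("cannot rank an empty score series")
    ordered = combined.sort_index().sort_values(ascending=False, kind="mergesort")
    n = len(ordered)
    table = pd.DataFrame(
        {
            "combined_score": ordered,
            "rank": np.arange(1, n + 1),
            "percentile": percentile_of_rank(np.arange(1, n + 1), n),
        }
    ).reindex(combined.index)
    return Ranking(table)


def _mean_rank_objective(S: np.ndarray, gene_order_key: np.ndarray, ref_idx: np.ndarray):
    """Build f(w) = mean rank of the references, matching rank_genes tie rules."""
    n = S.shape[0]
    ranks = np.empty(n, dtype=np.int64)

    def f(w: np.ndarray) -> float:
        if not np.any(w):
            return float(n)  # worst possible; keeps the search away from 0
        combined = S @ w
        order = np.lexsort((gene_order_key, -combined))
        ranks[order] = np.arange(1, n + 1)
        return float(ranks[ref_idx].mean())

    return f


def optimize_weights(
    scores: Sequence[ScoreVector],
    refs: ReferenceSet,
    cfg: OptimizationConfig = OptimizationConfig(),
) -> OptimizationResult:
    """Fit weights minimising the mean rank of the reference genes.

    Multi-start Nelder–Mead with a wide initial simplex and plateau-escaping
    restarts (the objective is piecewise constant, so vertex steps must be
    large enough to cross rank boundaries and a converged simplex may just be
    stranded). The best final point over all starts is returned, guaranteed
    no worse than any start — with the default unit-vector starts, no worse
    than any single method's mean rank. Ties between starts go to the lowest
    start index.
    """
    S, genes, methods = _score_matrix(scores)
    missing = refs.gene_ids - set(genes)
    if missing:
        raise ValueError(f"reference gene(s) absent from scores: {', '.join(sorted(missing))}")
    m = len(methods)
    ref_idx = np.flatnonzero(np.isin(genes, list(refs.gene_ids)))
    # ranks of gene ids in lexicographic order; lexsort tie key
    order_key = np.argsort(np.argsort(genes))
    f = _mean_rank_objective(S, order_key, ref_idx)

    if cfg.starts is not None:
        starts = [np.asarray(s, dtype=float) for s in cfg.starts]
        if not starts:
            raise ValueError("at least one start is required")
    else:
        starts = [np.ones(m), -np.ones(m)]
        for i in range(m):
            starts += [np.eye(m)[i], -np.eye(m)[i]]

    def _simplex_descend(x0: np.ndarray) -> tuple[np.ndarray, float]:
        best_x, best_f = np.asarray(x0, dtype=float), f(np.asarray(x0, dtype=float))
        for _ in range(cfg.max_restart_rounds):
            improved = False
            for scale in cfg.restart_scales:
                step = cfg.simplex_step * scale * max(1.0, float(np.abs(best_x).max()))
                simplex = np.vstack([best_x] + [best_x + step * np.eye(m)[j] for j in range(m)])
                res = minimize(
                    f,
                    best_x,
                    method="Nelder-Mead",
                    options={
                        "maxiter": cfg.max_iterations,
                        "initial_simplex": simplex,
                        "xatol": 1e-3,
                        "fatol": 1e-9,
                    },
                )
                if float(res.fun) < best_f - 1e-12:
                    best_x, best_f = np.asarray(res.x, dtype=float), float(res.fun)
                    improved = True
            if not improved:
                break
        return best_x, best_f

    best: tuple[float, int, np.ndarray] | None = None
    start_objectives = []
    for i, x0 in enumerate(starts):
        start_objectives.append(f(x0))
        candidate_x, candidate_f = _simplex_descend(x0)
        if best is None or candidate_f < best[0]:
            best = (candidate_f, i, candidate_x)

    assert best is not None
    obj, idx, w = best
    return OptimizationResult(
        weights=WeightVector(methods, tuple(float(v) for v in w)),
        objective=obj,
        start_objectives=start_objectives,
        best_start_index=idx,
    )


def loo_validate(
    scores: Sequence[ScoreVector],
    refs: ReferenceSet,
    cfg: OptimizationConfig = OptimizationConfig(),
) -> LooReport:
    """Leave-one-out assessment of the weight optimisation's bias.

    Each individual score already excludes a reference gene from its own
    value, so the only way a reference influences its own rank is through the
    fitted weights. For each reference r, weights are re-fitted on the other
    references and r's percentile in the resulting ranking is recorded.
    """
    if len(refs) < 2:
        raise ValueError("leave-one-out validation needs at least 2 reference genes")
    per_gene = {}
    for r in refs.ordered:
        held_in = ReferenceSet(refs.gene_ids - {r})
        result = optimize_weights(scores, held_in, cfg)
        ranking = rank_genes(combine_scores(scores, result.weights))
        per_gene[r] = ranking.percentile_of(r)
    return LooReport(
        mean_percentile=float(np.mean(list(per_gene.values()))),
        per_gene_percentile=per_gene,
    )


def evaluate_gene_set(ranking: Ranking, genes: Sequence[str] | set) -> GeneSetReport:
    """Percentile summary of a gene set plus a two-sided rank-sum test.

    The Mann–Whitney (Wilcoxon rank-sum) test compares the set's combined
    scores against all other genes; the normal approximation with tie
    correction is used beyond 50 genes total, the exact distribution below.
    """
    gene_list = sorted(set(genes))
    if not gene_list:
        raise ValueError("gene set is empty")
    unknown = [g for g in gene_list if g not in ranking.table.index]
    if unknown:
        raise ValueError(f"gene id(s) not in ranking: {', '.join(unknown)}")
    in_set = ranking.table.index.isin(gene_list)
    if in_set.all():
        raise ValueError("gene set covers every ranked gene; no background to test against")
    set_scores = ranking.table.loc[in_set, "combined_score"].to_numpy()
    rest_scores = ranking.table.loc[~in_set, "combined_score"].to_numpy()
    method = "asymptotic" if ranking.n > 50 else "auto"
    test = mannwhitneyu(set_scores, rest_scores, alternative="two-sided", method=method)
    percentiles = ranking.table.loc[in_set, "percentile"]
    return GeneSetReport(
        n_set=len(gene_list),
        mean_percentile=float(percentiles.mean()),
        min_percentile=float(percentiles.min()),
        max_percentile=float(percentiles.max()),
        p_value=float(test.pvalue),
    )


def bucket_ranking(ranking: Ranking, fraction: float = 0.025) -> list[list[str]]:
    """Partition the ranking into consecutive buckets of ``round(n·fraction)`` genes.

    Buckets are rank-ordered; the last bucket holds the remainder.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = ranking.n
    size = max(1, int(round(n * fraction)))
    genes = ranking.genes_by_rank
    return [genes[i : i + size] for i in range(0, n, size)]


def export_buckets(ranking: Ranking, out_dir, fraction: float = 0.025) -> list:
    """Write one plain-text gene list per bucket, named by its percentile range."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    buckets = bucket_ranking(ranking, fraction)
    n = ranking.n
    paths = []
    start_rank = 1
    for i, bucket in enumerate(buckets, start=1):
        hi = percentile_of_rank(start_rank, n)
        lo = percentile_of_rank(start_rank + len(bucket) - 1, n)
        path = out / f"bucket_{i:03d}_pct_{hi:.2f}-{lo:.2f}.txt"
        path.write_text("\n".join(bucket) + "\n")
        paths.append(path)
        start_rank += len(bucket)
    return paths
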