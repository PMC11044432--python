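"""Score combination, rank/percentile arithmetic, weight optimisation,
leave-one-out validation, gene-set evaluation and bucket partitioning."""

import numpy as np
import pandas as pd
import pytest

from telorank.ranking import (
    OptimizationConfig,
    WeightVector,
    bucket_ranking,
    combine_scores,
    evaluate_gene_set,
    export_buckets,
    loo_validate,
    optimize_weights,
    percentile_of_rank,
    rank_genes,
)
from telorank.reference_free_scores import ScoreVector
from telorank.reference_scores import ReferenceSet


def make_scores(matrix: np.ndarray, genes=None, methods=None) -> list[ScoreVector]:
    n, m = matrix.shape
    genes = genes or [f"g{i:03d}" for i in range(n)]
    methods = methods or [f"m{j}" for j in range(m)]
    return [
        ScoreVector(methods[j], pd.Series(matrix[:, j], index=genes), pd.Series(matrix[:, j], index=genes))
        for j in range(m)
    ]


class TestCombineScores:
    def test_unit_weight_reproduces_single_method(self):
        rng = np.random.default_rng(1)
        scores = make_scores(rng.random((30, 3)))
        w = WeightVector(("m0", "m1", "m2"), (0.0, 1.0, 0.0))
        combined = combine_scores(scores, w)
        assert rank_genes(combined).genes_by_rank == rank_genes(scores[1].scores).genes_by_rank

    def test_equal_weights_are_arithmetic_mean(self):
        scores = make_scores(np.array([[0.2, 0.8]]), genes=["g"])
        w = WeightVector(("m0", "m1"), (1.0, 1.0))
        assert combine_scores(scores, w)["g"] == pytest.approx(0.5)

    def test_signed_weights_use_absolute_normalizer(self):
        scores = make_scores(np.array([[0.2, 0.8]]), genes=["g"])
        w = WeightVector(("m0", "m1"), (1.0, -1.0))
        assert combine_scores(scores, w)["g"] == pytest.approx(-0.3)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            WeightVector(("m0", "m1"), (0.0, 0.0))

    def test_positive_scaling_preserves_and_negation_reverses_ranking(self):
        rng = np.random.default_rng(2)
        scores = make_scores(rng.random((25, 3)))
        w = WeightVector(("m0", "m1", "m2"), (1.0, -0.5, 0.3))
        w_scaled = WeightVector(w.methods, tuple(3.7 * x for x in w.weights))
        w_neg = WeightVector(w.methods, tuple(-x for x in w.weights))
        base = rank_genes(combine_scores(scores, w)).genes_by_rank
        assert rank_genes(combine_scores(scores, w_scaled)).genes_by_rank == base
        reversed_order = rank_genes(combine_scores(scores, w_neg)).genes_by_rank
        # score order reverses; exact list equality can differ only at ties,
        # and these random scores are tie-free
        assert reversed_order == base[::-1]

    def test_report_normalized_max_abs_is_one(self):
        w = WeightVector(("a", "b", "c"), (0.5, -2.0, 1.0))
        assert max(abs(x) for x in w.report_normalized) == 1.0
        assert w.report_normalized == (0.25, -1.0, 0.5)


class TestRankGenes:
    def test_percentile_formula_published_pairs(self):
        assert round(percentile_of_rank(417, 18475), 2) == 97.74
        assert round(percentile_of_rank(60, 18475), 2) == 99.68
        assert percentile_of_rank(18475, 18475) == 0.0

    def test_ties_broken_lexicographically(self):
        combined = pd.Series({"zeta": 0.5, "alpha": 0.5, "beta": 0.9})
        ranking = rank_genes(combined)
        assert ranking.genes_by_rank == ["beta", "alpha", "zeta"]
        assert ranking.rank_of("alpha") == 2

    def test_ranks_are_a_permutation(self):
        rng = np.random.default_rng(3)
        combined = pd.Series(rng.random(50), index=[f"g{i}" for i in range(50)])
        ranking = rank_genes(combined)
        assert sorted(ranking.table["rank"]) == list(range(1, 51))


class TestOptimizeWeights:
    def test_single_separating_method_reaches_global_optimum(self):
        # method m0 alone puts the refs at ranks 1..3: mean (k+1)/2 = 2 is
        # unimprovable, and the unit-start guarantee must find it
        n, k = 30, 3
        rng = np.random.default_rng(5)
        m0 = np.concatenate([np.linspace(1.0, 0.9, k), rng.uniform(0, 0.5, n - k)])
        other = rng.random((n, 2))
        scores = make_scores(np.column_stack([m0, other]))
        refs = ReferenceSet([f"g{i:03d}" for i in range(k)])
        result = optimize_weights(scores, refs)
        assert result.objective == pytest.approx((k + 1) / 2)

    def test_result_never_worse_than_any_start(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            scores = make_scores(rng.random((40, 4)))
            refs = ReferenceSet(list(rng.choice([f"g{i:03d}" for i in range(40)], 3, replace=False)))
            result = optimize_weights(scores, refs)
            assert result.objective <= min(result.start_objectives) + 1e-9

    def test_missing_reference_rejected(self):
        scores = make_scores(np.random.default_rng(0).random((10, 2)))
        with pytest.raises(ValueError, match="nope"):
            optimize_weights(scores, ReferenceSet(["nope"]))

    def test_custom_starts_respected(self):
        scores = make_scores(np.random.default_rng(1).random((10, 2)))
        refs = ReferenceSet(["g000"])
        cfg = OptimizationConfig(starts=((1.0, 0.0),))
        result = optimize_weights(scores, refs, cfg)
        assert len(result.start_objectives) == 1


class TestLooValidate:
    def test_exchangeable_references_match_full_optimization(self):
        # two references with identical, dominant score profiles: whichever
        # reference is held out, the fitted ranking puts both on top
        n = 20
        genes = [f"g{i:03d}" for i in range(n)]
        base = np.random.default_rng(7).uniform(0, 0.4, (n, 2))
        base[:2] = 1.0
        scores = make_scores(base, genes=genes)
        refs = ReferenceSet(genes[:2])
        full = optimize_weights(scores, refs)
        ranking = rank_genes(combine_scores(scores, full.weights))
        full_mean = np.mean([ranking.percentile_of(g) for g in refs.ordered])
        loo = loo_validate(scores, refs)
        assert loo.mean_percentile == pytest.approx(full_mean)

    def test_loo_never_beats_full_optimization_on_average(self):
        rng = np.random.default_rng(8)
        diffs = []
        for _ in range(20):
            S = rng.random((30, 3))
            refs_ids = [f"g{i:03d}" for i in rng.choice(30, 3, replace=False)]
            S[[int(r[1:]) for r in refs_ids]] += 0.3  # mild signal
            scores = make_scores(np.clip(S, 0, 1))
            refs = ReferenceSet(refs_ids)
            full = optimize_weights(scores, refs)
            ranking = rank_genes(combine_scores(scores, full.weights))
            full_mean = np.mean([ranking.percentile_of(g) for g in refs.ordered])
            diffs.append(full_mean - loo_validate(scores, refs).mean_percentile)
        assert np.mean(diffs) >= -1e-9  # optimisation bias is non-negative

    def test_two_reference_degenerate_case_runs(self):
        scores = make_scores(np.random.default_rng(9).random((15, 3)))
        report = loo_validate(scores, ReferenceSet(["g000", "g001"]))
        assert np.isfinite(report.mean_percentile)
        assert set(report.per_gene_percentile) == {"g000", "g001"}


def ranking_of_size(n: int):
    genes = [f"g{i:05d}" for i in range(1, n + 1)]
    combined = pd.Series(np.linspace(1.0, 0.0, n), index=genes)
    return rank_genes(combined)


class TestEvaluateGeneSet:
    def test_published_suggested_set_summary(self):
        ranking = ranking_of_size(18475)
        ranks = [60, 120, 262, 307, 333, 491, 551, 604, 751, 1944, 2118]
        genes = [ranking.genes_by_rank[r - 1] for r in ranks]
        report = evaluate_gene_set(ranking, genes)
        assert round(report.mean_percentile, 2) == 96.29
        assert round(report.min_percentile, 2) == 88.54
        assert round(report.max_percentile, 2) == 99.68
        assert report.p_value < 0.0001

    def test_p_value_decreases_with_top_k(self):
        ranking = ranking_of_size(200)
        pvals = [
            evaluate_gene_set(ranking, ranking.genes_by_rank[:k]).p_value
            for k in range(1, 21)
        ]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_error_cases(self):
        ranking = ranking_of_size(10)
        with pytest.raises(ValueError):
            evaluate_gene_set(ranking, [])
        with pytest.raises(ValueError, match="unknown_gene"):
            evaluate_gene_set(ranking, ["unknown_gene"])
        with pytest.raises(ValueError):
            evaluate_gene_set(ranking, ranking.genes_by_rank)


class TestBuckets:
    def test_quarter_fraction_of_100(self):
        buckets = bucket_ranking(ranking_of_size(100), 0.25)
        assert [len(b) for b in buckets] == [25, 25, 25, 25]

    def test_fraction_one_is_single_bucket(self):
        buckets = bucket_ranking(ranking_of_size(40), 1.0)
        assert len(buckets) == 1 and len(buckets[0]) == 40

    def test_last_bucket_holds_remainder(self):
        buckets = bucket_ranking(ranking_of_size(103), 0.25)
        assert [len(b) for b in buckets] == [26, 26, 26, 25]

    def test_buckets_are_rank_ordered_partition(self):
        ranking = ranking_of_size(97)
        buckets = bucket_ranking(ranking, 0.1)
        flat = [g for b in buckets for g in b]
        assert flat == ranking.genes_by_rank

    def test_export_writes_one_file_per_bucket(self, tmp_path):
        ranking = ranking_of_size(100)
        paths = export_buckets(ranking, tmp_path, 0.25)
        assert len(paths) == 4
        assert paths[0].read_text().splitlines() == ranking.genes_by_rank[:25]
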