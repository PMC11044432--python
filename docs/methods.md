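# Methods

This note documents the models and numerical choices behind `telorank`, the
parameters that matter, what the synthetic generator does and does not
emulate, and the known limitations.

## Telomeric distance and dataset construction

Telomeres are not annotated in genome assemblies, so a gene's telomeric
distance is approximated by its distance to the nearer end of the assembled
sequence: `min(start − chrom_start, chrom_end − end)`, with 1-based
inclusive coordinates (Ensembl convention). This under- or over-estimates
the true distance by the unassembled subtelomeric gap, identically for all
genes on the same arm, which is why all scores work on these distances
rather than raw coordinates. Strand is ignored; centromere positions are not
used (they are unavailable for most species' assemblies).

When a species carries several orthologs of one human gene, their distances
are collapsed to the median (even counts: mean of the central pair) — robust
to a single mis-annotated duplicate and deterministic. The collapsed
representative's chromosome and midpoint (the row realising the lower
median) are retained for the adjacency score, which needs physical
positions, not just distances.

Two inclusion filters run once, in a fixed order: genes with orthologs in
fewer than 25% of species are dropped first (judged against the pre-filter
species count), then species with orthologs for fewer than 50% of the
*remaining* genes. The order matters (a constructed counter-example is kept
as a regression test) and is not iterated to a fixed point; exactly-at-
threshold cases are kept, since the rule drops strictly-below. Gene and
species order is lexicographic throughout so every downstream result is
deterministic.

## Distance score (KDE mode)

Per gene, the typical telomeric distance across species is the mode of a
Gaussian kernel density estimate: bandwidth h = 0.9·min(sd, IQR/1.34)·n^(−1/5)
(the classic rule of thumb, with the standard fallbacks when the preferred
spread measure is zero), evaluated on 512 equally spaced grid points over
[min − 3h, max + 3h]. The mode is robust to the occasional rearranged
outlier in a way the mean is not. Ties go to the smaller location (the first
grid maximum). A constant sample has no defined bandwidth; its common value
is returned directly, which is the h → 0 limit of the estimator. The
coarse-grid mode is validated against a 10⁵-point fine-grid oracle in the
test suite (agreement within one coarse grid step).

Normalisation (here and for every method) is min–max over genes to [0, 1].
If all raw values coincide, everything maps to 0.5 so the weighted average
stays defined. The choice of min–max is isolated behind the `ScoreVector`
contract and can be swapped without touching the combination logic.

## Clustering score

Per gene, complete-linkage agglomerative clustering of its distances, tree
cut at height 1 Mb. Complete linkage is deliberate: the merge height equals
the cluster's maximum pairwise difference, so the cut makes "every cluster
spans at most 1 Mb" literally true — single or average linkage would not
guarantee that. The score is Σᵢ pᵢ·0.5^(i−1), clusters ordered by size
descending (ties by smallest member), pᵢ the fraction of orthologs in
cluster i. It is 1 exactly when all orthologs agree to within 1 Mb, lives in
(0, 1], and is invariant to shifting all distances and to species order. The
1 Mb span and 0.5 decay are configurable (`ClusterConfig`).

## Adjacency score

The distance to the nearest reference-gene ortholog substitutes the distance
to the telomere: per gene and species, the bp distance between gene midpoint
and nearest same-chromosome reference midpoint; the per-species values feed
the same KDE-mode machinery, and the normalised value is inverted so
proximity scores high. Cross-chromosome "distance" is meaningless in bp, so
species without a same-chromosome reference ortholog contribute nothing;
genes with no usable species at all are recorded in the score's `meta` and
treated as maximally distant. Midpoints (rather than starts or interval
gaps) are a documented choice. A reference gene is scored only against the
*other* references — with a single reference, the reference itself therefore
has no defined adjacency.

## Correlation score

Median, over references r ≠ g, of Spearman's ρ between the distance
profiles of g and r across the species where both are present. Pairs sharing
fewer than 3 species are skipped (rank correlation on fewer points is
degenerate; threshold configurable), as are undefined correlations from
constant profiles. Genes with no usable comparison get raw 0 (agnostic, not
anti-correlated). Being rank-based, the raw score is invariant under any
strictly monotone transform of the distances.

## Random-forest score

One regression forest per reference gene r, trained on every gene except r.
Features per gene: its telomeric distance in each species (Mb) with missing
orthologs encoded as −1 (distances are non-negative, so the sentinel is
separable by one split), plus the fraction of species with an ortholog.
Labels are 1 for the remaining references, 0 otherwise, with case weights
equalising total positive and negative weight; predictions of a regression
forest on 0/1 labels are leaf-averages and hence smooth scores in [0, 1].
r's reported score comes only from the model that never saw it; every
non-reference gene gets the mean over all models. Defaults: 500 trees,
⌊√(#features)⌋ features per split, fixed recorded seed; per-model seeds are
spawned from it, so results are reproducible bit-for-bit on one machine.
The label scheme (all non-references as negatives, no subsampling) and the
hyperparameters are this package's documented choices.

## Combined ranking and weight fitting

Combined score s(g) = Σₘ wₘ·sₘ(g) / Σₘ |wₘ|, linear in each method score;
weights may be negative so a method can count against a gene. Ranks are
assigned by descending score with lexicographic gene-id tie-breaks;
percentile = 100·(1 − rank/n), rounded to two decimals only at presentation.

Weights are fitted by minimising the mean rank of the reference genes. The
objective is piecewise constant in w — it changes only when two combined
scores cross — so gradient methods are useless and a simplex search can
converge on a plateau without being anywhere near the optimum. Two measures
address this: (i) multi-start from the all-ones vector, every unit vector,
*and their negations* — signed weights are part of the model, and
positive-orthant starts demonstrably strand the search; (ii) after each
Nelder–Mead run the search restarts from the incumbent with a fresh, large
simplex at several step scales until no restart improves. The unit-vector
starts make the result provably no worse than any single method's mean
rank. Exact fitted weight values are not expected to be reproducible across
optimiser implementations (plateaus mean many weight vectors share the same
objective); the objective value and the resulting ranking are the
meaningful outputs. Ties between starts go to the lowest start index.

Leave-one-out validation re-fits the weights once per held-out reference
(on the others) and records the held-out gene's percentile. The individual
scores already exclude each reference from its own value by construction,
so LOO isolates the one remaining channel of self-influence — the weight
fit. Scores are not recomputed inside the optimiser loop (they do not
depend on w).

Gene-set evaluation reports mean/min/max percentile and a two-sided
Mann–Whitney rank-sum test of the set's combined scores against all other
genes (normal approximation with tie correction above 50 genes total, exact
below). Bucket partitioning slices the ranking into consecutive buckets of
round(n·fraction) genes (default 2.5%; the last bucket holds the
remainder) and exports one plain-text gene list per bucket for external
enrichment tools.

## Synthetic data generator

The generator emulates the statistical structure of a cross-species
ortholog position export. Defaults define the standard fixture used
throughout the tests: 20 species × 5 chromosomes of 50–150 Mb, 500 genes,
10 planted genes at a target telomeric distance of 3 Mb (inside the ~15 Mb
window long-range telomeric control is thought to reach) with 100 kb
per-species jitter, 20% i.i.d. ortholog dropout, seed 42. Planted genes
keep their telomeric *distance* — the chromosome and arm are re-drawn
uniformly per species, matching what the scores measure. Background genes
are placed uniformly on a random chromosome per species: the
maximal-rearrangement null, under which no positional signal survives.

What the generator does **not** emulate: phylogenetic correlation between
species (rearrangements are independent per species, whereas real sister
taxa share them), chromosome-count and length distributions of real
genomes, gene-density gradients along arms, structured (non-i.i.d.)
ortholog missingness, and assembly-quality artefacts. Passing the recovery
tests therefore shows the method detects conserved telomeric distance
against an aggressive rearrangement null — not that it is robust to
phylogenetic confounding on real data.

Recovery analyses use the first 5 planted genes as references and evaluate
the held-out 5; the permutation control reruns the identical pipeline with
10 randomly drawn background genes relabelled as "planted". The control is
run at 12 draws with 100-tree forests — enough for a standard error of
about 3.7 percentile points on the held-out mean, so a genuine null
(centre 50) is comfortably distinguished from the planted signal
(centre ≈ 98).

## Numerical and degenerate-input conventions

- KDE: constant input → the common value; bandwidth fallbacks as above;
  mode ties → smallest location.
- Clustering: a single value is its own cluster; equal values merge at
  height 0.
- Normalisation: all-equal raw scores → 0.5 everywhere.
- Ranking ties → lexicographic gene id; optimiser start ties → lowest index.
- All-zero weight vectors are rejected; inside the optimiser the zero point
  is assigned the worst possible objective rather than an error.
- Filters that empty the dataset raise rather than return an empty object.

## Limitations

- The assembly-end approximation ignores unassembled subtelomeric sequence;
  distances are systematically biased per assembly, which cross-species
  aggregation mitigates but does not remove.
- Results depend on the genome-database release used to export positions;
  rankings are not expected to be identical across releases.
- The adjacency score is undefined for species lacking a same-chromosome
  reference ortholog; with few references this can silently shrink its
  effective species sample.
- Species are treated as exchangeable; no correction for phylogenetic
  non-independence or for replicative vs non-replicative aging is applied.
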