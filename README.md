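# telorank

Rank human genes by how strongly their chromosomal position — specifically
their distance to the telomeres — is conserved across species, and by how
well that positional behaviour matches a user-supplied reference gene set.

## The problem

Telomeres influence the expression of genes near chromosome ends, and
through long-range chromatin loops the *telomere position effect over long
distances* (TPE-OLD) can reach genes up to ~15 Mb away. Only a handful of
genes have been experimentally verified to be under this kind of telomeric
control. If telomeric distance matters functionally for a gene, that
distance should be constrained against chromosomal rearrangement — i.e.
preserved across species. `telorank` turns that hypothesis into a screen: it
scores every human gene by the cross-species behaviour of its telomeric
distance and combines the scores into a ranking in which genes positioned
like the verified reference genes rise to the top.

The input is a long-format table of ortholog positions (one row per human
gene × species), from which each gene's telomeric distance in each species
is approximated as the distance to the nearer end of the assembled sequence:
`d = min(start − chrom_start, chrom_end − end)`.

## The five scores and the combined ranking

For each gene g, over the species carrying an ortholog:

| method | what it measures |
|---|---|
| distance | mode of a Gaussian KDE over g's telomeric distances (typical position; high = far from telomeres) |
| clustering | decay-weighted cluster-size proportions Σᵢ pᵢ·0.5^(i−1) after complete-linkage clustering cut at 1 Mb (high = distance conserved) |
| adjacency | KDE-mode of the physical distance to the nearest reference-gene ortholog on the same chromosome, inverted (high = near the references) |
| correlation | median Spearman ρ between g's distance profile and each reference's across shared species |
| random forest | leave-one-reference-out forests trained to recognise the references' per-species distance patterns |

Each method's raw values are min–max normalised to [0, 1] over genes, and a
reference gene is always excluded from the computation of its own score.
The combined score is the signed weighted average

&nbsp;&nbsp;&nbsp;&nbsp;s(g) = Σₘ wₘ·sₘ(g) / Σₘ |wₘ|,

with weights fitted by minimising the mean rank of the reference genes
(multi-start Nelder–Mead; never worse than any single method). A gene at
rank r among n genes sits at percentile 100·(1 − r/n).

## Worked example

Generate a synthetic dataset (500 genes × 20 species; 10 genes planted at a
conserved 3 Mb telomeric distance, everything else uniformly rearranged),
use 5 planted genes as references, and check whether the other 5 are
recovered:

```bash
telorank simulate --n-genes 500 --n-species 20 --n-planted 10 --seed 42 --out-dir sim
# refs.txt     <- first 5 planted gene ids from sim/truth.json
# heldout.txt  <- the other 5
telorank score --dataset sim/dataset.tsv --references refs.txt --out-dir scores
telorank rank  --scores-dir scores --references refs.txt --optimize --out-dir ranked
telorank evaluate --ranking ranked/ranking.tsv --genes heldout.txt
```

prints

```json
{
 "n_set": 5,
 "mean_percentile": 98.39999999999999,
 "min_percentile": 98.0,
 "max_percentile": 98.8,
 "p_value": 0.00016298972009449092
}
```

The five held-out planted genes — which contributed nothing to training or
weight fitting — land at ranks 6–10 of 500 (mean percentile 98.4), far above
chance (two-sided Wilcoxon rank-sum p ≈ 1.6×10⁻⁴). The fitted weights and
their provenance are in `ranked/weights.json`; `telorank validate` runs
leave-one-out re-optimisation (mean percentile 98.56 on this fixture), and
`telorank buckets` exports consecutive fixed-fraction gene lists for
external enrichment tools.

The same commands work on a real Ensembl-style ortholog export with the
verified TPE-OLD genes (C1S, DSP, ISG15, SORBS2, TERT, PPP2R2C) as
`refs.txt`.

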