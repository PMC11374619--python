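# spibench

Rank, group and benchmark alternatives evaluated on a panel of indicators —
the composite-indicator workflow used to monitor road-safety performance
across countries, but applicable to any small-sample multi-criteria
benchmarking problem (states, hospitals, transit agencies, ...).

Given a decision matrix `R = (r_ij)` of `m` alternatives by `n` indicators,
each indicator marked *benefit* (larger is better) or *cost* (smaller is
better), the toolkit:

1. **Normalizes** the matrix (min-max by default; vector and z-score
   variants), folding the direction so larger always means better.
2. **Weights** the indicators objectively with the entropy weight method:
   `p_ij = x_ij / Σ_i x_ij`, `e_j = −(1/ln m) Σ_i p_ij ln p_ij`,
   `w_j = (1−e_j) / Σ_j (1−e_j)` — indicators whose distribution across
   alternatives is farther from uniform carry more information and get more
   weight. CRITIC and standard-deviation weights are available as variants.
3. **Aggregates** with PROMETHEE II outranking flows:
   `Π(a_i,a_k) = Σ_j w_j · max(x_ij − x_kj, 0)`,
   `Φ(a_i) = Φ⁺(a_i) − Φ⁻(a_i) = Σ_k Π(a_i,a_k) − Σ_k Π(a_k,a_i)`,
   ranking by descending net flow (net flows always sum to zero). TOPSIS
   and rank-sum-ratio (RSR) aggregation are available as variants.
4. **Groups** the alternatives into exactly K clusters: DBSCAN on the
   normalized (unweighted) Euclidean distance matrix, with `(ε, minPts)`
   chosen by exhaustive grid search maximizing the mean silhouette
   coefficient `s = (b−a)/max(a,b)`; when the grid yields no valid K-group
   noise-free partition, a deterministic small-sample two-round merge
   (nearest-neighbor linking, then smallest-average-distance merging)
   decides the partition.
5. **Benchmarks**: each group's member with the highest score is flagged
   best-in-class — the learning target for its peers.
6. **Stress-tests** the conclusions: Spearman correlations of rankings
   across normalization/weighting/aggregation swaps, adjusted-Rand
   agreement between partitions, and a signed per-indicator decomposition
   of achievement changes between two time points.

A synthetic-panel generator with planted quality tiers makes every stage
testable end to end, and the published score table of an 11-country
Southeast Asia road-safety study is bundled as a worked example.

## Worked example

```sh
python examples/02_full_pipeline_synthetic.py
```

```
panel: 11 alternatives x 20 indicators (4 cost-direction)
top-3 entropy weights: [0.065 0.062 0.056]
net flow sum (conservation, should be ~0): 0.00e+00

alternative     score  rank  group  is_benchmark
        A01  4.467826     1      1          True
        A02  4.414030     2      1         False
        ...
        A11 -5.177040    11      3         False

clustering source: fallback_merge (grid: 0/90000 valid combos)
planted tiers:   [1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3]
recovered groups:[1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3]
benchmarks (best-in-class per group): {1: 'A01', 2: 'A06', 3: 'A09'}
```

The score column holds PROMETHEE II net flows (higher = better), rank is
the competition rank, group the recovered quality tier, and the benchmark
flag marks each group's best-in-class. Here the recovered grouping matches
the planted three-tier structure exactly. With the default ε grid
(10⁻⁶..0.01) on 20-dimensional min-max data every point is DBSCAN noise —
typical pairwise distances far exceed 0.01 — so the two-round merge
produces the partition; `grid: 0/90000 valid combos` records that
honestly. Widen the grid (e.g. `eps_stop=2.0`) to see the DBSCAN route
adopted.

`examples/01_rank_published_scores.py` re-ranks the bundled published
score table (Spearman 1.000 against the published ranks for 2009, 2013,
2018 and 0.998 for 2015, where two countries tie at three printed
decimals), `examples/03_robustness_checks.py` prints the cross-variant
correlation tables, and `examples/04_achievement_decomposition.py` shows
the year-over-year decomposition.

The same workflow is scriptable from a shell:

```sh
spibench simulate --m 11 --n 20 --seed 1 --out-dir syn
spibench evaluate syn/matrix.csv syn/spec.csv --out-dir results
spibench robustness syn/matrix.csv syn/spec.csv --axis weighting
```

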