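# Methods

## The model

The pipeline evaluates `m` alternatives on `n` indicators in four stages:
normalization, objective weighting, outranking aggregation, and density
grouping with benchmarking. It assumes indicator directions are known
(benefit vs cost), values are finite, and `m` is small (order 10) — the
small-sample regime drives several design choices below.

**Normalization.** Min-max is the primary method: benefit columns map via
`(r − min)/(max − min)`, cost columns via `(max − r)/(max − min)`, so all
values land in [0, 1] with direction folded. The vector variant divides by
the column Euclidean norm (cost columns use the `1 − r/‖r‖` complement — a
standard MCDM convention, chosen here because no canonical cost rule
exists for vector normalization; the choice is recorded in result
metadata). The z-score variant standardizes with the sample (n−1)
standard deviation and negates cost columns, for which direction folding
is exact: a cost column and its negated benefit twin produce identical
output. A constant column is division-by-zero territory under min-max and
vector scaling; it is mapped to all zeros with a logged warning and
receives weight zero downstream, consistent with the entropy logic that a
no-variation indicator carries no discriminating information.

**Entropy weights.** Proportions `p_ij = x_ij/Σ_i x_ij` use the convention
`0·ln 0 := 0`, which is required rather than cosmetic: min-max places an
exact zero in every column. An all-zero column gets entropy 1 and weight
0; if *every* column is constant the method fails loudly ("no informative
indicator"). Entropy is undefined for negative input, but the robustness
protocol fixes entropy weighting while varying normalization, and z-score
output is signed. `entropy_weights` stays strict; the pipeline
resolves the clash by shifting any column with negative entries to a zero
minimum (logged) before the entropy stage only. The shift preserves each
column's spread and keeps the proportions well defined.

**CRITIC** uses the canonical form `w_j ∝ σ_j Σ_k (1 − ρ_jk)` with Pearson
correlations and sample standard deviations; correlation with a constant
column is defined as 0. It needs `m ≥ 3` (correlations from two points
are ±1 identically).

**PROMETHEE II.** The preference function is the usual criterion — the
positive part of the coordinate difference, with no indifference or
preference thresholds (none are warranted for normalized indicator data,
and thresholds would add free parameters to a method whose appeal is
having none). Flows are plain sums over opponents, *not* divided by m−1:
the published score magnitudes this package reproduces (e.g. 5.648 on an
11-alternative panel) are only consistent with unnormalized sums. Net
flows sum to zero by algebraic identity; the test suite enforces this to
1e-9 and the acceptance script reports the residual (~1e-16).

**Ranking.** Descending-score competition ranking: ties share the
smallest applicable rank, and output rows order by rank then
lexicographic id. The published 2015 column prints two countries at the
same 3-decimal score with distinct ranks; that collision is an artifact
of printed precision, which the bundled data documents.

**TOPSIS / RSR.** Both consume the pipeline's direction-folded normalized
matrix (rather than re-normalizing internally): `v_ij = w_j x_ij`, ideal
and anti-ideal are columnwise extremes, closeness `C = d⁻/(d⁺+d⁻)`; RSR
uses columnwise midranks with rank m for the best value,
`RSR_i = Σ_j w_j R_ij / m`. If all alternatives coincide, TOPSIS
closeness is conventionally 0.5 for everyone.

## Grouping

Distances are Euclidean on the normalized **unweighted** matrix: weights
encode importance for ranking, while grouping should reflect raw
similarity of profiles. This is why a country's rank and its group can
disagree — they are computed from differently scaled spaces.

**DBSCAN** is the classical algorithm on a precomputed distance matrix:
core point iff its ε-neighborhood (itself included — this choice shifts
minPts semantics and is stated deliberately) holds ≥ minPts points;
clusters grow breadth-first from cores in index order; border points
attach to the first core that reaches them; everything unreached is
noise. This matches the reference implementation in scikit-learn exactly
(verified point-for-point on random instances in the test suite).

**Grid search** evaluates every (ε, minPts) combination on the lattice
(default 10⁻⁶..0.01 step 10⁻⁶ × minPts 2..10 = 90,000 combinations),
scoring each by the mean silhouette over non-noise points (singleton
clusters score 0; labelings with fewer than two clusters are invalid and
skipped). Ties break toward smaller minPts, then smaller ε. Because the
DBSCAN outcome only changes when ε crosses one of the m(m−1)/2 pairwise
distances, results are computed once per distance interval and shared
across the ε values inside it — an exact optimization that makes the full
default lattice run in milliseconds; selection is identical to direct
evaluation (asserted against an exhaustive loop in the tests).

On min-max data in [0,1]^20, typical pairwise distances are well above
0.01, so the default ε grid usually yields *no* valid combination. The
grid is therefore configurable, and `n_valid_combos` is reported rather
than silently patched. The adopted rule is: the grid winner's labeling is
used only when it has exactly `target_k` clusters and no noise
(`source="dbscan"`); otherwise the two-round merge decides
(`source="fallback_merge"`). This honors both the grid-search step and
the small-sample merge step without inventing a hybrid.

**Two-round merge.** Round one unions each point with its nearest
neighbor (ties to the smallest index); round two repeatedly merges the
two groups with the smallest average inter-group distance (the mean over
all cross pairs) until exactly K groups remain. If round one already
yields ≤ K groups, the procedure restarts from singletons and runs
round-two merging only — this guarantees exactly K and makes the
boundaries exact (K=m gives all singletons, K=1 one group). All
tie-breaks are lexicographic on smallest member index, making the whole
path deterministic and permutation-equivariant up to relabeling.

**Benchmarks.** Final group ids 1..K are ordered by descending best
member score (so group 1 contains the overall top scorer, matching the
I/II/III convention of published tables); each group's best-in-class is
its score argmax, ties to the lexicographically smallest id.

## Robustness protocol

One stage is swapped at a time, the other two held fixed; rankings are
compared with Spearman's ρ (midrank ties — the tables compare *rankings*,
so correlation is computed on ranks, not scores). Partitions are compared
with the adjusted Rand index; ARI was chosen because published grouping
comparisons are qualitative and partition agreement needs a
chance-corrected statistic (ARI is 1 iff identical, ~0 at chance).
Significance stars are out of scope: permutation p-values at m=11 would
be a new analysis, not a reproduction. The achievement decomposition is
the raw cell-wise difference between two labeled matrices with cost
columns negated, so positive always reads as improvement; it is exactly
antisymmetric in its arguments.

## Synthetic panels

The generator emulates the *shape* of a regional safety-indicator panel:
11 alternatives × 20 indicators by default, 20% cost-direction columns,
heterogeneous affine column scales (drawn once per seed), and K=3 planted
quality tiers. Tier centers sit at the same coordinate in every latent
dimension, spaced `separation` apart (tier 1 highest), giving
componentwise dominance between tiers; within-tier noise is isotropic
Gaussian (sd `noise_sd`) clipped to [0,1]. Defaults `separation=0.30`,
`noise_sd=0.06` put tiers five within-tier standard deviations apart —
distinct but not trivially separated, the regime where both the ranking
and the grouping should succeed essentially always, which the recovery
tests quantify (ARI 1.0 in ≥95/100 seeds; mean Spearman against the
planted quality order ≥0.9). What the generator does **not** emulate:
real marginal distributions of WHO/World Bank style indicators,
cross-indicator correlation structure, expert-scored ordinal columns, or
missingness. Passing recovery tests therefore demonstrate correctness of
the machinery under clean planted structure, not performance on real
survey data.

All randomness flows through `numpy.random.default_rng(seed)` held in the
generator spec; the pipeline itself is deterministic.

## Problem sizes and numerical choices

Tests and the acceptance script run at the study's natural scale (m=11,
n=20; 50-instance oracle sweeps; 100-seed recovery runs; the full 90,000
combination grid), which completes in seconds thanks to the interval
memoization. Tolerances: exact-formula oracles at 1e-12, cross-library
agreement at 1e-9, conservation at 1e-9. Matrix CSV output uses `%.17g`
so write→read round-trips are bit-exact.

## Known limitations

- Entropy weights ignore practical significance; expert-adjusted weights
  are supported only insofar as any fixed weight vector can be supplied
  programmatically to the aggregation functions.
- The usual-criterion preference function makes PROMETHEE II scores
  scale-dependent on the normalization; this is inherent and is exactly
  what the robustness protocol measures.
- With ε capped at 0.01 the default grid cannot validate clusters on
  min-max data of this dimensionality; the fallback merge then always
  decides. The grid is exposed rather than silently rescaled.
- ARI on 11 points is coarse; small membership changes move it in large
  steps.
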