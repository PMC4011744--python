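# Methods

## Problem and data model

`otupairs` analyzes co-occurrence structure in surveys where hundreds of
host individuals (here: tree seedlings of two congeneric *Quercus* species)
are each profiled for the presence of fungal OTUs in their roots. The core
data object is a binary community matrix: samples (seedlings) in rows, OTUs
in columns, 1 = detected. Such matrices are extremely sparse (mean
per-sample richness of 3–4 OTUs out of ~300) with a long-tailed occupancy
distribution — a handful of common OTUs and a large majority seen in one or
two seedlings.

## Filtering read-count tables

Raw inputs are read-count tables plus per-sample metadata. Binarization is
preceded by three filters, applied in a fixed order because the second
depends on per-sample totals:

1. **Read-depth filter** (`min_reads`, default 20): samples with a total
   strictly below the threshold are removed — a low-coverage sample cannot
   distinguish absence from non-detection.
2. **Within-sample relative-abundance filter** (`minor_threshold`, default
   5%): inside each sample, an OTU contributing strictly less than the
   threshold of that sample's reads is zeroed. This suppresses
   sequencing-error OTUs and equalizes effective detection effort across
   samples with very different depths.
3. **Contamination filter**: samples flagged in the metadata (e.g. non-host
   plant DNA detected) are dropped.

Both numeric filters use strict `<`, so a value exactly at the threshold is
retained. OTU columns left without occurrences are dropped, so "number of
OTUs" downstream always refers to taxa present in the final matrix.
Exclusions are set operations on samples; a sample failing several criteria
is removed once.

## Pair scores

For OTUs *i*, *j* with occurrences R_i, R_j, co-occurrence count S and N
samples:

- checkerboard score C = (R_i − S)(R_j − S) — large when the pair avoids
  sharing samples (segregation);
- togetherness score T = S(N + S − R_i − R_j) — large when joint presences
  and joint absences dominate (aggregation).

Given fixed margins, S is confined to [Smin, Smax] with
Smin = max(0, R_i+R_j−N), Smax = min(R_i, R_j); C is strictly decreasing
and T strictly increasing in S on that interval. Scores are standardized by
their margin-feasible maximum — C/C(Smin) and T/T(Smax) — which is the only
normalization for which 0 and 1 are the attainable extremes for *every*
margin configuration. When a maximum is 0 (an OTU absent everywhere or
present everywhere), the standardized score is defined as 0 rather than
NaN; such OTUs never pass pair screening anyway.

## Null models and randomization tests

The default null is **fixed-fixed**: randomized matrices preserve both row
sums (sample richness) and column sums (OTU occupancy). It is the
conservative standard for checkerboard analyses because it attributes
nothing to richness or occupancy heterogeneity. Sampling uses the curveball
trade chain: two rows are picked at random and the columns held by exactly
one of them are re-dealt uniformly. Defaults: `burn_in` = 5 × fill and
`thin` = 2 × fill trades between saved matrices, where fill is the number
of ones. The thinning factor was set from a mixing diagnostic: at 1 × fill
the lag-1 autocorrelation of the community mean standardized C score was
0.03–0.06, at 2 × fill it is indistinguishable from 0 (< 0.02), meeting the
< 0.05 independence contract. Two alternative nulls (`fixed_rows`,
`fixed_fill_equiprobable`) are available for sensitivity analysis; the
analysis default is fixed-fixed.

Sampler correctness is verified against an exact enumerator of the margin
space (uniform over all matrices with the given margins): chain frequencies
pass chi-square uniformity tests on every small margin signature, and
Monte-Carlo pair P values at M = 10,000 agree with exact enumeration P
within ±0.02.

**Pair screening.** Pairs enter testing only if each member occurs in at
least `min_occurrence` samples and the occurrence sum reaches
`min_pair_sum` (defaults 5 and 25 per host dataset; 10 and 50 for pooled
two-host analyses). Below these counts the null score distribution is
pinned at its extremes and the randomization test has essentially no power.

**Tests.** Per-dataset pair tests are one-sided in the upper tail (large
standardized C = segregation, large standardized T = aggregation), with the
add-one estimator P = (1 + b)/(1 + M); the observed arrangement counts as
one realization, so P ≥ 1/(M+1) and the test is exact-valid. Host-contrast
tests compare standardized scores between two host subsets
(Δ = score_A − score_B) for pairs passing screening in both subsets; the
null permutes host labels across samples preserving group sizes
(the minimal exchangeability assumption), two-sided on |Δ|.
Community-level tests use the mean standardized score over all unordered
pairs of OTUs present in a subset (no pair screening — the statistic is a
community property), one-sided, with SES = (obs − null mean)/null SD.
Benjamini–Hochberg FDR adjustment is applied within each
(test, dataset, score type) family. M defaults to 10,000 (configurable
upward; P-value resolution is 1/(M+1)).

## Diversity and spatial statistics

- **Sample-based rarefaction** (Mao Tau): exact hypergeometric expectation
  E[S_k] = Σ_s [1 − C(N−n_s, k)/C(N, k)]. The SD uses the exact
  joint-absence covariance C(N−u_st, k)/C(N, k) (u_st = samples holding s
  or t), i.e. the true finite-population variance of subsampling the
  observed matrix; it matches a resampling oracle to Monte-Carlo error.
- **Raup–Crick dissimilarity**: for each sample pair, null communities
  preserve each sample's richness and draw species with probability
  proportional to pool occupancy; D = [#(S_null > S_obs) +
  0.5·#(S_null = S_obs)]/reps ∈ [0, 1], 0.5 = chance. Because the null
  distribution of shared richness depends only on the richness pair, draws
  are cached per (k1, k2), making all-pairs matrices cheap. The two null
  communities of a pair are independent draw sets.
- **Mantel correlogram**: per geographic distance class (default width
  2 m), the statistic is minus the Pearson correlation between community
  distances and the class-membership indicator, so positive r = positive
  autocorrelation; P per class by permutation of sample identities
  (one-sided, positive), progressive Bonferroni correction across classes.
- **Moran's I** with weights w = 1/d (not row-standardized), expectation
  exactly −1/(n−1), normality-assumption variance, normal-approximation P.
  Coincident points are an error (jitter or exclude); applied per OTU with
  an occurrence floor (default 10).
- **PERMANOVA**: pseudo-F and permutation P via scikit-bio; R² computed
  from the distance-based sum-of-squares partition (truncated at 0, since
  semimetric dissimilarities like Raup–Crick can make the partition
  marginally negative).
- **PERMDISP**: per-sample distances to group centroids in principal
  coordinate space with Anderson's negative-eigenvalue correction
  (corrected squared distances truncated at 0), one-way F on those
  distances, P by permuting the distances; per-group mean distances are
  reported. The F statistic matches scikit-bio's `permdisp` (centroid
  mode) to numerical precision.
- **CLAM classification**: each OTU's occurrence counts (y_A, y_B) are
  tested with one-sided exact binomial tests at the supermajority threshold
  K = 2/3 on the effort-corrected expected count fraction
  q(π) = πn_A/(πn_A + (1−π)n_B): specialist of A if P(Y ≥ y_A | q(K)) ≤ α,
  specialist of B symmetrically, generalist if both one-third bounds are
  rejected; otherwise — or when counts are below the coverage limit
  (default 10) in both groups — too rare. Defaults α = 0.001, K = 2/3.
  Occurrence counts (seedlings occupied) are used as "abundance",
  consistent with the presence/absence basis of the whole analysis; read
  counts can be supplied instead. This is the supermajority procedure in
  its exact-binomial form; implementations using a coverage-corrected
  normal approximation (e.g. vegan's `clamtest`) can classify borderline
  species differently.
- **Richness Welch t**: Welch two-sample t with Satterthwaite df on
  per-sample richness (scipy).

## Synthetic data generator

The generator is the test bed for every stage. Per sample it draws planar
coordinates in a 300 m × 200 m rectangle (minimum spacing 1 m,
best-effort), a host label, a presence vector, and read counts:

- per-OTU baseline occurrence probabilities follow Beta(a, b) (long tail:
  defaults per preset), optionally shifted per host on the log-odds scale;
  designated OTUs can instead be pinned to a fixed occupancy
  (`fixed_occupancy`), which recovery experiments use to plant couplings
  at a controlled expression level;
- a zero-mean latent spatial field with exp(−d/range) correlation
  (default range 8 m) is added to the log-odds, producing short-range
  compositional autocorrelation of the kind Mantel correlograms detect;
- designated disjoint OTU pairs are drawn from the exact bivariate
  Bernoulli law with given marginals and odds ratio ψ (the joint-presence
  cell solves the Plackett quadratic; ψ may be host-specific), so planted
  aggregation (ψ > 1) and segregation (ψ < 1) are exactly calibrated;
- reads for present OTUs are 1 + NegBin(mean ≈ 40, dispersion 2), giving
  per-sample totals ≈ 130 at richness 3–4, so the 20-read and 5% filters
  act non-trivially.

`emulate_study_shape` is a frozen preset reproducing the shape of a
two-host root survey: 249 + 188 samples, ≈ 319 observed OTUs, mean richness
≈ 3.0–3.4, ≈ 30–40 OTUs with ≥ 10 occurrences. Its Beta parameters
(1.15, 159.1) and base OTU count (392) were solved by moment matching of
E[Σp], E[#occ ≥ 1] and E[#occ ≥ 10] under Binomial(437, p) with the
logit-normal field marginalized by Gauss–Hermite quadrature
(`solve_emulation_beta` reproduces the computation).

What the generator does **not** emulate: taxonomic structure (guild labels
are arbitrary), read-depth correlation with richness, chimeras/index
hopping, and any interaction structure beyond disjoint pairwise odds-ratio
couplings. Passing tests therefore demonstrate statistical correctness of
the machinery under a known model, not ecological validity on real surveys.

## Verification surface and problem sizes

The test suite and `scripts/acceptance.py` verify, end to end:

1. exhaustive score-grid properties for N ≤ 12 (bounds, monotonicity,
   symmetry, extreme attainment);
2. curveball uniformity vs exact enumeration on all small margin
   signatures, and MC-vs-exact P agreement (±0.02 at M = 10,000);
3. type-I error of the pair tests on independent-OTU matrices
   (N = 200, 30 OTUs, M = 2,000): rejection at α = 0.05 stays ≤ 0.07;
4. planted-coupling recovery (N = 400, 30 OTUs, M = 2,000, occupancy
   ≈ 0.2): three ψ = 8 pairs occupy the top three T ranks, and a ψ = 1/8
   pair is the top C hit, in ≥ 80% of replicates. The segregation check is
   rank-1 rather than exact top-3: with small expected overlap the odds
   ratio bounds the attainable co-occurrence deficit, so the weakest
   planted pair is detectably but not always dominantly segregated;
5. host-contrast validity: nominal rejection under shared couplings, and
   ≥ 80% top-rank recovery of a host-specific ψ = 8 coupling
   (N = 200 per host). The coupled pair is planted at a pinned occupancy
   of 0.30 (`fixed_occupancy`): a coupling planted at an occupancy of
   0.1 or below is statistically inexpressible at this sample size under
   any method, so the detection property is evaluated at the occupancy of
   a common OTU pair, analogous to the ≈ 0.2 pinning in the pair-recovery
   design;
6. the diversity layer's identities (rarefaction vs resampling, Moran
   expectation −1/(n−1) exactly, Raup–Crick chance level 0.5 under its own
   null).

Replicate counts in the shipped suite (15–40 matrices per check) are
desk-scale choices that keep the default run in minutes while leaving the
thresholds meaningful; the per-matrix conditions (sample sizes, OTU
numbers, M) are as stated above.

## Numerical and degenerate-input choices

- P values always include the observed arrangement: P = (1+b)/(1+M).
- Standardized scores of degenerate margins are 0, never NaN.
- Ties in null-vs-observed comparisons count toward the tail (observed
  score compared with a 1e-12 tolerance).
- The exact enumerator refuses margin spaces larger than a cap (default
  10^6 matrices) and directs the caller to Monte-Carlo mode.
- Raup–Crick with a zero-richness sample returns 0.5 (chance) with a
  warning.
- Curveball seeds are derived through `SeedSequence`, so any user seed maps
  to a valid 31-bit kernel seed and distinct stages never share streams.
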