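# Methods

This note documents the statistical models and procedures implemented in
`pondiv`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic data generator does and does not emulate.

## Data model and assumptions

The universal input is a pond × species matrix of non-negative integer
counts with every pond assigned to one of exactly two regions, plus a
species × trait binary incidence matrix over a fixed 17-trait catalogue
(guilds LowPro/HighPro/Motile/Planktonic; life-forms Mobile, Benthic,
ATT_Hig/Med/Low, MucoTub, Pedunculate, Colonial, Pioneer; biovolume classes
c1/c2/c3/c5, with user extensions such as c4 accepted). Counts are assumed
to come from a fixed counting depth per pond (valves identified until a
quota, e.g. 400, is reached), so no rarefaction to equal depth is applied
anywhere: depths are equal by design. Analyses that the literature defines
on presence-absence (Baselga partition, Raup–Crick, IndVal, trait
frequencies, networks) binarize internally or require a binarized matrix;
abundance-weighted analyses (Bray–Curtis, FDis/FDiv weighting, SES.MPD) use
the raw counts as relative weights, which makes them invariant to the
counting depth. Duplicate trait columns (perfectly collinear traits, which
occur in real coding tables) are tolerated throughout.

## Two-sample inference

The rank-sum test reports W, the Mann–Whitney U of the first sample (ties
counted 0.5), matching the convention of common statistical software. For
combined samples of at most 12 observations the two-sided p-value is exact:
all C(n, n_x) group assignments of the pooled values are enumerated and
|U − n_x·n_y/2| compared, which handles ties correctly; larger samples use
the normal approximation with continuity and tie correction. The cutoff
keeps study-sized comparisons (12 vs 12 ponds → n = 24) on the approximate
path only when enumeration would be expensive, while every per-trait test
in small designs is exact. Effect sizes are Cliff's δ by exhaustive pair
counting.

## Accumulation curves and the AUC permutation test

The exact accumulation curve uses the hypergeometric expectation
E[S_m] = Σ_s [1 − C(n−f_s, m)/C(n, m)] over per-species pond frequencies
f_s; the random method averages any per-subset metric over random pond
orderings and is the only option for non-richness metrics. The AUC is the
**plain sum** of per-step expected values, not a trapezoid — this matches
the definition the pipeline was built to reproduce and only changes the
statistic by an affine factor.

The permutation test reshuffles pond-to-region labels (group sizes
preserved), recomputes both curves and the AUC difference. The p-value is
(1 + k)/(1 + N) with k the number of permutations whose **absolute**
difference reaches the observed absolute difference; the reported tail
("greater"/"less") is a label taken from the observed sign. Counting by
magnitude is essential: with the direction chosen after seeing the data, a
sign-restricted count would have size ≈ 2α under the null. Calibration was
verified by simulation (empirical size 0.050 over 500 exchangeable-region
datasets at α = 0.05; power 1.00 over 100 draws of the default contrast) —
both checks run in the test suite at those sizes.

For the default richness metric the test is evaluated by an exact
vectorized identity: the per-species AUC contribution depends only on f_s,
so per-group AUC = Σ_s g(f_s) with g precomputed per group size, and each
permutation is one boolean matrix product. This is why the protocol-scale
10,000 permutations are the default for the taxonomic test.

## Functional diversity

Binary Gower distance is the mismatch proportion; constant columns are
retained (contributing zero) and logged. The trait space is the PCA score
space of the column-centred incidence matrix (eigendecomposition of the
covariance, axes ordered by variance, deterministic sign: the
largest-magnitude loading of each axis is positive), retaining
k = min(10, S−1, T) axes. PCA scores are used directly as Euclidean
coordinates for the indices — the pipeline's stated design — rather than a
Gower→PCoA embedding, so parity with dbFD-style implementations is
approximate by construction.

* **FRic** is the raw convex-hull volume of the present species (no
  standardization by a global maximum; values are therefore comparable only
  within one trait space).
* **FDis** is the abundance-weighted mean distance to the
  abundance-weighted centroid, over all retained axes.
* **FDiv** follows Villéger: distances d_i of all present species to the
  gravity centre of the *hull vertices*, d̄ their unweighted mean,
  FDiv = (Σw_i(d_i−d̄) + d̄)/(Σw_i|d_i−d̄| + d̄) ∈ [0, 1].

**Hull dimensionality.** Hull-based indices are computed on the first
k′ = min(4, axes retained, #present − 1) axes. The cap at 4 axes is a
deliberate numerical choice: binary-trait score clouds are strongly
clustered, and Qhull's facet count (hence run time) explodes combinatorially
with dimension (measured ~45× slower at 6 axes than 4 for ~100 species),
which would make hull evaluation inside permutation loops intractable;
moreover a volume estimated from a few dozen points in 8–10 dimensions is
statistically meaningless. On degeneracy (coplanar cloud) the dimension is
reduced once more and the index is flagged undefined if the hull still
fails. FDis is unaffected and uses all retained axes. Ponds with fewer than
2 (FRic) or 3 (FDiv) species are flagged undefined rather than zero-filled.

Functional rarefaction pools abundances over pond prefixes in each of
n_reps random orderings and evaluates the three indices **in the fixed
scope-level trait space**, so each ordering's FRic curve is monotone by
hull nesting; undefined values are excluded from per-step means with a
logged count. The functional AUC permutation test rebuilds the trait space
from each permuted group's own species pool (per-site filtering), using a
numpy fast path; package defaults are 200 permutations × 10 orderings per
curve, chosen so a full pipeline run stays in the minutes range on one
core.

## β structure

PERMANOVA uses the McArdle–Anderson partition of squared dissimilarities
(SS_total = Σ_{i<j} d²_ij/N, within-group analogue per group, pseudo-F with
(a−1, N−a) degrees of freedom), free label permutation, (1+k)/(1+N). On
1-D Euclidean distances it reproduces classical one-way ANOVA F exactly
(asserted in tests, together with a cross-check against an independent
implementation). β-dispersion embeds the distance matrix by principal
coordinates, handles negative eigenvalues by Anderson's imaginary-part
correction (squared centroid distance = real part − imaginary part, clipped
at zero), and applies classical one-way ANOVA to the centroid distances;
groups use centroids, not spatial medians. NMDS is non-metric (isotonic
regression on dissimilarity ranks, iterative majorization), best of 20
random starts, reporting Kruskal stress-1; the convergence tolerance is
1e-12 on the relative stress decrease because looser values demonstrably
stall at stress ~1e-4 even when an exact embedding exists.

The Baselga partition is implemented from the published pairwise and
multiple-site formulas; β_SOR = β_SIM + β_SNE holds to machine precision by
construction and is asserted on random matrices. Pairs of empty communities
are flagged undefined.

**Raup–Crick.** For each pond pair, null communities preserve each pond's
richness and draw species without replacement with probability proportional
to occurrence frequency across all ponds plus a smoothing constant
(default 1; uniform weighting available). Sampling uses the Gumbel top-k
construction, which is exactly sequential weighted sampling without
replacement but vectorizes over randomizations.
β_RC = P(null shared > observed) + 0.5·P(null shared = observed), so 0.5 is
the stochastic-assembly expectation, values near 1 mean less sharing than
expected (deterministic turnover) and values near 0 more sharing. This
orientation is fixed by the boundary case (two identical full-pool ponds →
β_RC = 0.5) and is asserted in tests. With uniform weights the null shared
count is hypergeometric, giving an exact evaluation mode that the
Monte-Carlo mode is checked against, alongside a brute-force enumeration
oracle on a 4-species pool.

## Functional assembly

SES.MPD: observed abundance-weighted mean pairwise Gower distance per pond,
MPD = Σ_{i≠j} w_i w_j d_ij / Σ_{i≠j} w_i w_j; the null shuffles species
labels on the distance matrix (rows and columns jointly, one shuffle per
run applied to every pond), 999 runs by default; SES = (obs − null mean)/
null sd, flagged undefined when the null sd vanishes (e.g. constant
distances); p_rank is the tie-averaged rank of the observed value among
observed + null over (runs + 1). An exhaustive mode enumerates all S!
label permutations for small pools and is compared against brute force in
tests. A presence-only weighting toggle exists.

The overlap test computes the PCA space **once** from the pooled species
set and holds it fixed; only region membership is permuted, preserving the
observed counts of A-only / B-only / shared species (shared species are
members of both hulls). The union hull is therefore constant across
permutations. The p-value is the plain proportion of permuted overlap
indices ≥ observed (no +1 correction here, unlike the other tests — both
conventions are implemented and this one is the default for this test
only). Degenerate permuted hulls are resampled once, then tallied as
missing. The index can be negative when the two hulls are disjoint and
their union is larger than their sum; 0 still reads "no overlap" and 1
"complete overlap".

## Indicators and networks

IndVal is group-equalized (IndVal.g): specificity A_g normalizes mean
occurrence by group size, fidelity B_g is the occupied fraction of the
group's ponds, stat = √(A·B) for the best single group (only the two
singleton groups are candidates); p-values permute pond labels with
(1+k)/(1+N). Analysis runs on presence-absence. Trait site means multiply
the binary occurrence matrix by the trait matrix, average per region, and
compare regions per trait with the rank-sum test; raw p-values are reported
at α = 0.05 with an optional Benjamini–Hochberg toggle left off by default.

Networks connect species to the traits they carry. Density is reported in
two conventions: the generic unipartite |E|/(n(n−1)/2) — the scale on which
the motivating analysis reported its values — and the bipartite-correct
|E|/(S·T). Modularity is Newman's Q of a Louvain partition, best of 10
seeded restarts (deterministic given the seed). The null model draws
contingency tables with the observed row and column sums by the Patefield
algorithm; because integer margins can produce cells > 1, null tables are
binarized before graph reconstruction by default (a keep-weights mode
computes weighted modularity instead). Edgeless null tables score 0 and are
logged. p = (1 + #{null Q ≥ observed Q})/(1 + N).

## Synthetic metacommunity generator

The generator emulates the motivating study design and is the basis of all
calibration tests: two regions × 12 ponds, regional species pools of 60 and
100 species, 20% of the union pool shared between regions, per-species pond
occupancy Bernoulli(0.3) (re-drawn while a pond is empty), within-pond
relative abundances from normalized lognormal(σ = 1) draws, and counts from
a single multinomial of 400 valves per pond — so column sums are exactly
the counting depth. Traits: exactly one guild and one biovolume class per
species (categorical draws) plus independent Bernoulli life-form traits,
with probabilities biased by pool membership (shared species average the
two regional probabilities); default biases follow the direction of the
reported regional trait contrasts. All draws come from one seeded
generator stream in documented order (pools → traits → ponds), so a config
and seed fully determine the output. The null-pair variant forces one
shared pool and identical parameters, giving exchangeable regions for
type-I studies.

Pool sizes and occupancy give mean per-pond richness ≈ 18 vs 30 and a
γ contrast in the same direction as the study; the abundance model is a
stand-in (the study reports no abundance distribution), and the generator
has **no** spatial autocorrelation, temporal/hydroperiod dynamics,
phylogenetic trait signal, or detection error. Passing calibration tests
on this generator therefore demonstrates correctness of the inference
machinery under idealized sampling, not robustness to those real-data
features.

## Problem sizes in the test suite

Monte-Carlo suite sizes were fixed in advance at scales that make the
binomial error bounds meaningful on one core: AUC-test size over 500 null
datasets at 200 permutations; power over 100 contrast datasets at 999
permutations; the FRic-AUC size check over 30 reduced datasets (6 ponds per
region, 25-species pools, 49 permutations × 4 orderings) with a wide
binomial bound; planted-block modularity at 999 nulls and the unstructured
median-p check over 100 datasets at 49 nulls. The full suite runs in under
two minutes.

## Known limitations

* dbFD parity is approximate: the indices are computed in PCA score space
  with a capped hull dimension, and FRic is unstandardized, so absolute
  FRic scales differ from dbFD defaults.
* The exact Raup–Crick mode requires uniform weights; the
  frequency-weighted null is Monte-Carlo only.
* PERMANOVA supports one factor and free permutation (no strata or nested
  designs).
* The overlap test needs ≥ 4 non-degenerate species per region and three
  informative PCA axes; narrower trait tables should lower `n_axes`.
* IndVal considers singleton site groups only (the two-region case), not
  group combinations.
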