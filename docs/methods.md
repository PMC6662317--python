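# Methods

This note records the statistical model, the conventions the implementation
pins down where the literature leaves latitude, and what the synthetic data
do and do not establish.

## Trait space

Traits are declared, never inferred: a schema maps every column to
{continuous, binary} and to a functional category (food type, foraging
stratum/substrate, foraging method, activity period, mixed flock). The
default schema carries one continuous trait (mean body mass, grams, valid
range enforced > 0) and 25 binary traits. Validation requires each species
to have at least one food type and one foraging stratum; forest dependency
is categorical {high, medium, low}.

Gower dissimilarity gives every trait equal weight. Binary traits are
symmetric by default (a shared absence of a foraging capability is treated
as informative agreement); an asymmetric variant that drops double absences
from the pair's denominator is available as a schema flag. The continuous
trait is range-normalized with the range computed **once on the regional
pool** and reused for every subgroup, so specialist and generalist
dissimilarities live on the same scale. Body mass enters untransformed by
default; a `log10_mass` flag exists and changes results. Gower output is in
[0, 1]; 1 is reached only by species opposite in every trait with masses at
the pool extremes.

## Indices

* **FD**: the community's species are re-clustered with average linkage
  (UPGMA) on their block of the pool distance matrix, and FD is the sum of
  all branch segments: each merge at height h with children previously
  merged at h₁, h₂ contributes (h − h₁) + (h − h₂), leaves at height 0.
  Nothing above the root is counted. This is the tree-height convention
  (for two species at distance 0.6, FD = 1.2); the per-community
  re-clustering (rather than pruning one pool dendrogram) is deliberate:
  S = 1 gives FD = 0. Ties in minimal pair distance break by species-label
  order, so runs are bit-reproducible.
* **FEve**: species coordinates are principal coordinates of the
  Cailliez-corrected pool dissimilarity matrix. The additive constant c is
  the largest real eigenvalue of the standard 2n × 2n companion system;
  values below numerical noise (1e−7 × max d) clamp to 0, and all axes with
  eigenvalue > 1e−8 are retained, so corrected distances are embedded
  exactly rather than truncated to a fixed axis count. One embedding is
  computed for the full table and *restricted* to communities and
  subgroups — restriction preserves the corrected inter-point distances
  exactly, keeps groups comparable, and makes label-shuffle nulls a pure
  row permutation. On the community's Euclidean minimum spanning tree
  (Prim's algorithm, deterministic index-order tie-breaks, zero-length
  edges retained), EW_l = dist/(p_i + p_j), PEW_l = EW_l/ΣEW, and
  FEve = (Σ min(PEW_l, 1/(S−1)) − 1/(S−1)) / (1 − 1/(S−1)). FEve is
  undefined (missing, never 0) below S = 3; communities that fall under
  that threshold after subgrouping are excluded pairwise from FEve
  contrasts with a logged count. If all community members coincide in
  trait space FEve returns 1 by convention (ΣEW = 0).
* **Rao** Q = Σᵢⱼ d_ij p_i p_j with both orders counted; **Simpson** is the
  same sum with d ≡ 1 off-diagonal, i.e. 1 − Σp². Both are Jost-corrected
  (1/(1 − x)) onto the equivalent-community scale, where D_eq equals S for
  uniform abundances. The correction rejects x ≥ 1 (saturated index).
* FD is presence-based; FEve, Rao and Simpson weight species by relative
  abundance within the (possibly subgroup-restricted) community.

## Null model and SES

Each landscape is its own regional pool: the species recorded anywhere in
that landscape. A null replicate permutes species labels over trait rows of
the pool, leaving occupancy, richness and abundances untouched; since the
pool geometry is fixed, a replicate is implemented as an index permutation
of the distance matrix and coordinate rows — the Gower matrix and the
corrected embedding are computed once. Subgroup membership travels with the
trait rows, so it is re-derived inside every replicate; the subgroup's
richness at a site therefore varies across replicates, which is the
intended consequence of shuffling the full pool. (A
`shuffle_within_subgroup` flag permutes labels only among subgroup members,
freezing membership, for sensitivity analysis.) Replicates where an index
is undefined (e.g. FEve with a shuffled subgroup below 3 species) are
dropped from the null sample and the reported `n_null` counts the valid
ones. SES = (observed − null mean)/null sd (sample sd); a degenerate null
(sd = 0, e.g. sites containing the whole pool) yields a missing SES with a
warning. One RNG stream is spawned per (landscape, index, subgroup) from
the master seed, keyed by stable identifiers, so adding an index or
subgroup never changes the others' draws. Default n_null = 999; the test
suite and acceptance script use 199 for throughput, which widens
Monte-Carlo noise on single SES values by ~√(200/1000) but leaves their
mean and calibration properties intact.

## Inference

Habitat contrasts use the difference in group means under group-label
permutation, two-sided; enumeration is exhaustive when C(n₁+n₂, n₁) ≤
n_iter (default 100 000), otherwise Monte-Carlo with the observed
arrangement counted in numerator and denominator, so p is never 0. Assembly
tests are one-sample t tests of SES against μ = 0 run **per habitat** ×
subgroup × index (the habitat-specific question is the one the contrasts
feed). Each landscape yields 15 SES contrasts (5 subgroups × 3 indices),
emitted explicitly; with that multiplicity only p < 0.01 is flagged
`significant`, with 0.05/0.10 annotation tiers and no FDR correction.
Decoupling uses Spearman rank correlations (mid-ranks) between taxonomic
(S, D_eq) and functional (SES) metrics per landscape × habitat × subgroup.
Moran's I uses inverse-distance weights, row-normalized, expectation
−1/(n−1), two-sided normal approximation with the randomization
(kurtosis-adjusted) variance; coincident sites raise an error advising
jitter or exclusion.

## Synthetic data

The generator emulates the survey structure the analysis was designed for:
a regional pool (default 150 species) with independent Bernoulli binary
traits (per-trait prevalence ~ Beta(2, 2)), lognormal body mass (log-mean
3.6, log-sd 1.3, clipped to [2, 2172] g — median ≈ 37 g with a long right
tail, the familiar shape of an avifaunal mass distribution), forest
dependency drawn (0.3, 0.4, 0.3) over high/medium/low, and food/stratum
constraints enforced by rejection. Two landscapes hold 12 + 6 and 4 + 4
forest/agroforestry sites in disjoint bounding boxes with a minimum
inter-site spacing. Per-site richness is normal (mean 35, sd 6, truncated
at 3) — large enough that subgroup analyses stay defined, small enough that
a 26-site pipeline run stays interactive. Abundances are lognormal counts,
independent of traits by default. Assembly rules per habitat:

* *neutral* — uniform sampling without replacement;
* *filtering* — inclusion probability ∝ exp(−g²/(2σ_f²)) with g the Gower
  distance to the habitat's optimum phenotype (a pool species drawn per
  habitat, so σ_f is interpretable in Gower units; default 0.08, which is
  strong filtering relative to a typical pool mean distance of ~0.3; as
  σ_f → ∞ the rule converges to neutral);
* *limiting similarity* — greedy max–min: from a random start, repeatedly
  add the species maximizing its minimum distance to those chosen.

What the generator does **not** emulate: phylogenetic or ecological trait
covariance (traits are independent), trait-linked abundances (optional
hook), spatial autocorrelation (none injected, so Moran's I should be
null), detection error, or real avifaunal trait frequencies. Passing tests
therefore establish the statistical machinery — unbiased nulls, calibrated
error rates, recovery of injected assembly signals — not conclusions about
any real bird community.

## Problem sizes and verification

The acceptance-style tests use: 50 replicate neutral landscapes (pool 150,
n_null = 199) to check |mean SES| < 0.15 per index, SES sd in (0.8, 1.2),
and the one-sample t rejection count at α = 0.01 inside its binomial 95%
interval; 25 filtering replicates (σ_f = 0.08, landscape A) requiring
agroforestry sesFD and sesRao significantly negative, forests null, and the
habitat contrast conclusive in ≥ 80% of replicates; 10 limiting-similarity
replicates for the positive direction. `scripts/acceptance.py` recomputes
smaller versions of the same quantities (12/12/6 replicates) from scratch.
Index implementations are tested against independent oracles: naive double
sums (Rao), per-trait arithmetic (Gower), brute-force spanning-tree
enumeration (MST), step-by-step EW/PEW evaluation (FEve), closed forms
(inverse Simpson, Jost, Moran expectation), and exhaustive enumeration
(permutation p-values).

## Known limitations

* FD on communities of hundreds of species re-clusters per site and per
  null replicate; the permutation trick keeps this O(S² log S) per
  evaluation, but very large pools (>10³ species) would warrant a pruned
  pool-dendrogram FD variant (available behind the per-community default).
* The Cailliez companion-matrix eigenproblem is dense (2n × 2n); pools
  beyond ~2000 species would need an iterative solver.
* Permutation p-values for unbalanced tiny groups are coarse; the smallest
  achievable two-sided p with 4 + 4 sites is 2/70.
* Medium forest-dependency species belong to neither the specialist nor the
  generalist subgroup; where a survey's classification differs, reclassify
  before loading.
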