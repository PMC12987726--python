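# Methods

This note records the models the package implements, the conventions chosen
where the underlying procedures left room, and what the synthetic-data tests
do and do not establish.

## Signature model and extraction

A mutation catalogue `X` (samples × channels, non-negative integers) is
modeled as `X_cp ~ Poisson((S A)_cp)` with `S` (channels × K) column-stochastic
signature profiles and `A` (K × samples) non-negative activities. Extraction
minimizes the generalized Kullback–Leibler divergence — the Poisson deviance
up to constants — by the classical multiplicative updates from random uniform
initialization. The objective is asserted non-increasing every 100
iterations; convergence is a relative objective decrease below `tol`
(default 1e-8) with an iteration cap of 10,000. This is a deliberately
desk-scale solver: production extractions in large studies run the same
update rule for orders of magnitude more iterations with GMM-based matrix
normalization; we omit the normalization (it is not specified reproducibly
and matters mainly for extreme hypermutators) and use raw catalogues.

Per candidate K, `n_restarts` seeded restarts (seed + restart index) are run;
the best-log-likelihood restart is the consensus. Other restarts are matched
to it by greedy maximum-cosine pairing (equivalent to Hungarian assignment on
well-separated signatures, which the tests confirm); **stability** is the
mean matched cosine and the per-channel variance of matched profiles across
restarts is kept — it later supplies the combiner's inverse-variance weights.

Model selection:

- **AIC rule** (used for SV signatures): `AIC = 2K(n+M) − 2·Σ(X log λ − λ)`,
  the parameter count `K(n+M)` plus twice the negative constant-free Poisson
  log-likelihood. The log-factorial constant is omitted; it cancels between
  candidate K. Minimum AIC wins, ties toward smaller K.
- **Stability rule** (SBS/DBS/ID/CN custom): the largest K whose stability
  meets `min_stability` (default 0.8) *and* whose per-sample KL reconstruction
  errors improve over K−1 by a one-sided Wilcoxon rank-sum test at p < 0.05,
  falling back to the smallest candidate. The rank-sum step is our stated
  approximation to the replicate comparison used by production extractors;
  on noisy Poisson fixtures the default threshold can admit planted-K+1
  (the extra component buys a genuine error improvement at stability ≈ 0.89),
  which is the intended behavior of a threshold rule, not a defect.

## Cross-cohort combiner

Decomposition solves non-negative least squares of a profile on the reference
matrix; the decomposability criterion is cosine > 0.8 between the profile and
its normalized reconstruction. Non-decomposable signatures are grouped by
scanning all pairs in descending cosine order: a cross-cohort pair above 0.8
opens a set when neither member is assigned; a signature joins an existing
set only when it exceeds 0.8 cosine with *every* member and its cohort is not
yet represented. Each set merges to a consensus by a per-channel
inverse-variance weighted mean (`w = 1/max(var, 1e-6)`), renormalized — the
printed form of the set equation sums weights over channels and members
jointly, which we read as the per-channel mean, the only reading that keeps
the consensus a probability vector. The set with the smallest maximum cosine
to any current reference signature is admitted (one per iteration, maximizing
linear independence of additions) and the loop repeats until everything
decomposes. A non-decomposable signature that can join no cross-cohort set is
admitted directly — without this the loop would stall on singletons.
Cosine ties break lexicographically by (cohort, name) for determinism.

The leave-one-out **composability audit** reconstructs each reference
signature from all others by the same NNLS/cosine machinery, quantifying the
linear dependence that one-at-a-time admission cannot prevent. The audit of
the COSMIC v3.3 SBS catalogue requires the COSMIC files (distributed under
their own terms, not bundled); the test suite runs it when the files are
placed under `data/`, and the acceptance script reports the audit on a
synthetic reference constructed to contain exactly one dependent member
(expected composable fraction 1/8, which it recovers).

## VAF-peak copy-number QC

Only autosomal segments in the five simple clonal states 1:1, 1:0, 2:2, 2:1,
2:0 are used; a state holding under 5% of SNVs is not considered.
Multiplicity 2 is legal only where the major allele has two copies. Expected
peak locations, peak-wise purity inversion, the weighted purity re-estimate
`ρ_new = Σ nᵢρᵢ/(n_all qᵢ)` and the concordance metric η follow the formulas
in the README; the inversion is the exact algebraic inverse of the peak
formula (tested to 1e-12). Conventions adopted where the procedure is
underdetermined:

- KDE uses a Gaussian kernel with Silverman bandwidth on VAFs in (0,1),
  evaluated on a 512-point grid; the peak-density threshold 0.3 is applied on
  the absolute density scale. At least 10 VAFs are required, else the sample
  fails as insufficient data.
- Peak matching pairs the greatest-multiplicity expectation with the greatest
  observed VAF, the rest by nearest VAF. The single worst pair (largest
  |Δ VAF|) is discarded per sample across all states whenever more than one
  expected peak was considered; |Δ| ties discard the lower expected peak.
  Because discarded peaks keep their weight in the denominator, ρ_new is a
  sub-convex combination (weights sum to ≤ 1) — an intentional conservatism
  of the printed weighting, which is why purity recovery is benchmarked on
  diploid-dominated samples where no peak is discarded.
- Peak-wise purities are clamped to (0, 1] before averaging.
- CCF cluster summaries (the clonal-cluster and super-clonal criteria) are
  accepted as inputs; for synthetic data a helper assigns each SNV to its
  nearest expected-multiplicity peak and mode-finds the CCFs by 1-D KDE. The
  clustering engine of the original pipeline is not re-implemented.
- The tetraploid criterion (a multiplicity-1 peak observed in 2:2 regions,
  within 0.05 VAF of its expectation) binds only when a majority of
  considered SNVs lie in 2:2.
- η is computed against the current attempt's purity, so a corrected purity
  can pass on the next attempt; after three failed attempts the sample is
  excluded (a result state, not an error).

## Event calling

*Interleaved* is defined as: two intrachromosomal rearrangements whose
breakpoint intervals overlap with neither nested in the other; a
rearrangement counts if it is interleaved with at least one cluster member
(the ≥1-partner reading; pairwise-mutual interleaving is stricter and not
implied by common usage). Oscillation scans maximal runs with no two adjacent
segments at equal total copy number, per chromosome in genomic order, looking
for a 4-window on ≤2 states or a 5-window on ≤3 states. The orientation
criterion is a χ² goodness-of-fit on 3 df against equal quarters over
duplication-like, deletion-like, head-to-head and tail-to-tail inversion
joins, Benjamini–Hochberg-corrected at FDR 0.2 across all clusters evaluated
together; a cluster is chromothripsis only if the test is *not* rejected.
The chromoplexy chain graph has one node per breakpoint, an edge for each
rearrangement's own join and proximity edges between breakpoints of different
rearrangements within 1 Mb on a chromosome; the chain criterion asks for a
connected component touching ≥3 chromosomes. Footprint balance is consumed as
an input annotation. Missing segments make the oscillation criterion
indeterminate and the call is flagged rather than guessed.

## Association engine

Covariates are log(age), sex and three germline principal components,
standardized; samples with missing covariates are dropped listwise. The
activity model is an NB2 GLM (log link, MLE dispersion); failure to converge
within 100 iterations, or an invalid dispersion, falls back to Poisson with
the family recorded. The score statistic is evaluated at the null fit
(target coefficient 0, nuisance at the null MLE): `u = Σ xᵢ(yᵢ−μᵢ)/(1+αμᵢ)`,
scaled by the *efficient* information for the target coefficient — its
marginal information minus the covariate-explained part — so a target
collinear with the design is singular by construction. The dCRT compares the
real target's score with scores of 100 targets resampled from the
target-given-covariates model (logistic for binary targets, Poisson for
counts, the capped three-component sum for gene inactivation) through a 1-df
χ² on the standardized difference. Exchangeability of real and resampled
scores under the null is what delivers calibration; the three mock designs
measure it: NB-clean activities (mock 1), heavy-tailed lognormal-Poisson
activities the NB cannot fit (mock 2), and within-cohort permutations of
inactivation targets across cohorts with different rates (mock 3). Mock
component rates default to p_germline = 0.05, μ_somatic = 0.2, p_loh = 0.5
and the mock-1 NB uses unit covariate coefficients with θ = 1. The naive
NB/P Wilks likelihood-ratio p-value is computed alongside as the comparator
the dCRT replaces; under mocks 2–3 it rejects ~25% at α = 0.05 where the
dCRT stays nominal.

The logistic arm binarizes activity at the cohort median (zero activity is
always 0; values at the median map to 1, per the `A_i < median` rule) and
tests the target by a Wilks LRT; quasi-separation is flagged, not hidden.
Survival uses a Cox PH model on standardized log(activity+1) plus covariates,
with a Wald p for the activity term, a Schoenfeld-residual proportional-
hazards test (rank time transform) and a Ljung–Box test on the residual
autocorrelation; results are reportable only when the PH p exceeds 0.01.

## Timing and aggregation

Attribution fractions are undefined where no active signature covers a
channel; encountering a nonzero count there is an error, not a silent zero.
Attribution conserves totals exactly per sample and timing class. The
Mann–Whitney comparison pools all other signatures' subclonal fractions in
the cohort; ties take midranks, with exact-enumeration p-values for small
untied groups and the asymptotic test otherwise. The scaled mean rank divides
the mean midrank by the pooled count N — under this convention all-tied data
yields (N+1)/(2N) and cohort mean ranks average 0.5 + 1/(2N), both → 0.5 —
and samples with fewer than 20 subclonal mutations for the signature are
excluded from the test (not from attribution). Early/late-clonal splits reuse
the same operations with the two timing classes relabeled.

Aggregation squares χ²₁ z-scores across cohorts into a groups-df χ²
statistic and back-converts the aggregate p to a single-df z that carries the
common direction; evidence sets whose study-wide-significant members disagree
in sign are excluded, only positive sets are aggregated for DNA-repair-gene
targets, the min-p binomial correction `1−(1−p_min)^T` handles multiple tests
per cohort, and targets with aggregate p beyond 20× the family minimum are
discarded as confounded.

## Synthetic data: what it does and does not show

The generators reproduce the statistical *structure* the pipeline assumes —
NB activities with covariate effects on a standardized five-covariate design,
Poisson channel counts from S·A, binomial read sampling of VAFs at known
purity, multinomial signature-of-origin assignment before binomial subclonal
thinning, the capped composite inactivation, and event-caller fixtures built
to satisfy or violate one named criterion. Defaults: Dirichlet(0.1) reference
profiles (sparse and mutually distinguishable; real signature catalogues are
not Dirichlet draws), baseline activity 200 mutations per signature
(mid-range burden), NB size θ = 1 (strong overdispersion, stated explicitly
as mean–size parameterization since variance = μ + μ²/θ), age ~ N(60, 10).
Passing tests therefore demonstrate correctness of the algorithms under
their own model assumptions and robustness of the dCRT beyond them (mock 2/3
violate the NB deliberately); they do not demonstrate recovery on real
tumors, where signatures overlap in channel support (attribution smearing),
catalogues carry artifact signatures, and VAF distributions mix subclonal
structure into the peaks. Timing recovery in particular is exact only for
disjoint-support signatures; overlapping supports bias per-signature
fractions toward the cohort mean, which is a property of expected-fraction
attribution itself, not of this implementation.

## Problem sizes

Defaults used by the test suite and acceptance script: extraction recovery on
a 200-sample, 32-channel catalogue with 4 planted signatures (K = 1..8, 5
restarts); purity recovery over 50 samples of 3,000 SNVs at depth 80; dCRT
calibration at 200 samples × 500 replicates per mock; orientation-test
calibration over 1,000 clusters of 24 rearrangements. These sizes give stable
pass/fail behavior at interactive runtimes while remaining far below
cohort-scale inputs, which the same code paths accept unchanged.
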