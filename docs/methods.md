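# Methods

This note documents the statistical procedures implemented in `hapstruct`,
the defaults and units of their tunable parameters, the synthetic data the
test suite runs on, and the numerical and design choices made where more
than one convention exists.

## Data model

The exchange objects are an `Alignment` (equal-length nucleotide sequences
over {A, C, G, T, N, -} with sample ids and population labels), a
`HaplotypeCatalog` (distinct sequences named SP1, SP2, … in decreasing
pooled-count order, ties broken by first occurrence), and a `CountTable`
(haplotype × population non-negative integer matrix whose column sums are
the per-population sample sizes). Published relative-frequency tables are
converted to counts cell-wise by nearest-integer (half-up) rounding of
frequency × n; the reconstruction is validated against the declared sample
sizes and refuses to proceed on a mismatch (explicit per-cell overrides are
supported). For tables printed to three decimals from integer counts this
rounding is exact, which is why frequency-derived statistics reproduce to
full precision. Per-population frequency sums are accepted within ±0.01 of
1 to tolerate printed rounding.

Haplotype identity uses `strict` matching by default (N and - are ordinary
states; the intended inputs are complete sequences), with a
`pairwise_ignore` policy available that merges sequences agreeing at every
jointly non-missing site (greedy in input order against class
representatives; note this relation is not transitive, so the greedy order
is part of the definition). Distance computations always exclude
jointly-missing sites (`pairwise_ignore`).

## Distances

TN93 distances use the standard maximum-likelihood distance form with the
two transition classes (A↔G, C↔T) separated and empirical base frequencies
estimated from the pooled data, weighted by haplotype counts (the
conventional estimator; an unweighted variant is available by omitting the
counts). Saturated pairs (any logarithm argument ≤ 0) raise an error rather
than clamping — a silently clamped distance would bias the downstream
variance partition. No gamma rate heterogeneity is applied (none is part of
the reference analysis); the identity metric (0/1) and raw step counts
(differing, jointly non-missing sites) cover the frequency-based statistics
and network/mismatch computations respectively.

## Diversity and neutrality

* h: Nei's unbiased estimator with Nei's (1987) sampling variance of
  heterozygosity.
* π: mean pairwise distance per site with the n/(n−1) correction; variance
  per the standard total variance of π (Nei 1987 eq. 10.7, stochastic plus
  sampling term). By default π uses TN93 per-site distances; a raw
  (p-distance) variant is exposed (`metric="raw"`), since either convention
  appears in published tables and they differ only in the 4th decimal at
  the diversity levels involved here.
* Tajima's D with the published constants; S = 0 is reported as *undefined*
  (an exception), not as 0.
* Fu's Fs = ln(S′/(1−S′)), S′ = P(K ≥ k_obs | θ, n) under the Ewens sampling
  distribution, θ set to the observed mean pairwise difference (θ_π).
  Unsigned Stirling numbers of the first kind are computed exactly as
  Python integers (they reach ~10⁹⁰⁰ at n = 430) and the tail sum is
  evaluated in arbitrary-precision arithmetic (mpmath, working precision
  scaled with n). S′ equal to 0 or 1 within precision raises a signed
  sentinel error carrying S′ — the statistic is never silently clamped.
* Null p-values: constant-size coalescent samples with infinite-sites
  mutation at θ = θ̂_π (configurable), simulated with msprime (haploid
  samples, unit population size, mutation rate θ/2 on a unit genome so the
  expected pairwise difference equals θ). p is the lower-tail proportion of
  simulated statistics ≤ the observed one; replicates with S = 0 score the
  statistic as 0. Significance conventions: α = 0.05 for D, α = 0.02 for
  Fs. Default 20,000 simulations; the test suite and examples scale this
  down (120–2,000) and the pipeline logs a warning whenever a Monte-Carlo
  setting is below the reference defaults.

## Mismatch distributions and the sudden-expansion model

The mismatch distribution counts raw pairwise differences over all
unordered individual pairs, expanded combinatorially from haplotype counts.
The sudden-expansion expectation F_j(τ, θ₀, θ₁) is computed in closed form
by mixing the Poisson difference count over the two-epoch exponential
coalescence density:

    F_j = Ĝ_j(θ₁) · P[Pois(βτ) > j] + e^(−τ/θ₁) Σ_{i≤j} Pois(j−i; τ) Ĝ_i(θ₀)

with β = (θ₁+1)/θ₁ and Ĝ_j(θ) = θʲ/(θ+1)^(j+1) the equilibrium geometric
law (evaluated in log space; θ₀ = 0 allowed). Probability mass beyond the
truncated support is folded into the last class, so the vector sums to 1
for any parameters.

Fitting minimises the sum of squared deviations between observed class
frequencies and F over (τ, θ₀, θ₁) with bounds τ ≥ 0, 0 ≤ θ₀ ≤ θ₁ ≤ 9999
(the conventional cap), by L-BFGS-B from eight starts (a moment-based start
at the distribution mean plus seeded random starts). Single-class
distributions short-circuit to τ = 0 and are flagged degenerate.

Harpending's raggedness index is r = Σ_{i=1}^{d+1} (xᵢ − xᵢ₋₁)² over
classes 0…d with a terminal zero class appended; there is no leading
(x₀ − 0)² term, and trailing zero classes do not change r. Its p-value is a
parametric bootstrap: coalescent samples of size n under the fitted
demography (recent size 1, mutation rate θ₁/2, size change to θ₀/θ₁ at time
τ/θ₁), p = proportion of simulated r ≥ observed; p > 0.05 is reported as
"consistent with expansion". The same simulation engine backs the
parameter-recovery tests.

A known limitation: with single-locus data all pairwise comparisons share
one genealogy, so the least-squares τ̂ is strongly over-dispersed relative
to the multinomial ideal (replicated coalescent fits at τ = 3, θ₀ = 0.5,
θ₁ = 50, n = 200 recover τ within ±1 in only ≈ 80 % of replicates, with a
slight upward median bias, whereas fits to multinomial draws from the model
itself recover it essentially always). The acceptance check of the fitting
routine therefore uses model (multinomial) draws; the coalescent-replicate
dispersion is asserted only through a robust median test.

## AMOVA and permutation inference

The one-group variance partition on squared distances follows the standard
sums-of-squares construction: SS_total from all individual pairs divided by
N, SS_within from within-population pairs divided by the population size,
σ_b² = SS_w/(N−J), n′ = (N − Σn_j²/N)/(J−1), σ_a² = (SS_a/(J−1) − σ_b²)/n′,
fixation index σ_a²/(σ_a²+σ_b²). With 0/1 identity distances this is the
frequency-based F_ST; with TN93 distances it is Φ_ST. Negative variance
components are retained (not truncated), so small negative pairwise indices
are reproducible. All pair sums are evaluated on the haplotype-count level
(c·D²·c quadratic forms), which the tests verify against explicit
individual-level enumeration.

Permutation inference reassigns *individuals* among populations with sizes
fixed (vectorised in blocks of 2,000 via batched bincounts and quadratic
forms) and reports p as the plain proportion of permuted indices ≥ the
observed one, deliberately without the (x+1)/(n+1) correction so that a
reported p of exactly 0 is possible, matching the convention of the
reference software. Default 20,000 permutations; Monte-Carlo sd
√(p(1−p)/n_perm) is attached. Pairwise matrices give every pair an
independent spawned seed stream, so results are order-independent, and
attach Holm (sequential Bonferroni) family-wise flags (first threshold
α/k, e.g. 0.05/6 = 0.0083 for four populations).

The Mantel test correlates lower-triangle entries under joint row/column
permutations of one matrix, one-tailed for positive association, again
without the +1 correction; with ≤ 7 labels and enough requested
permutations it switches to exact enumeration of all n! orderings.

## Subsample robustness and rarefaction

The robustness simulation draws simple random subsamples (without
replacement — the subsample haplotype counts are multivariate
hypergeometric by construction) of the focal population at each requested
size, keeps the other population intact, and reruns the two-population
permutation AMOVA per replicate. The contradiction likelihood per size is
the proportion of replicate p-values on the opposite side of α = 0.05 from
the full-sample call. Reference settings are 10,000 replicates × 20,000
permutations at sizes 150/100/60; the library accepts any scaled-down
setting and the pipeline warns when one is used. Reports are
bit-reproducible under a fixed seed.

Hurlbert rarefaction is evaluated exactly for every m = 1…N by accumulating
each binomial-coefficient ratio as a running product of rational factors
(no factorials are formed, so there is no overflow at any N). A
permutation-based Monte-Carlo curve (nested subsamples from whole-sample
shuffles, giving all m per draw) serves as the cross-check.

## Haplotype networks

The 95 % connection limit is the largest step count j (capped at the
maximum observed pairwise distance) whose probability of being free of
superimposed change is ≥ the confidence level. That probability is
evaluated under an explicit occupancy model: the true number of mutations
M separating a pair is Poisson with mean estimated from the data's mean
pairwise divergence (Jukes–Cantor corrected to expected hits), mutations
hit sites uniformly, and a connection is parsimonious when all M hits land
on distinct sites; Bayes over M ≥ j gives P(parsimony | j observed
differences). This is a transparent approximation to the classical
statistical-parsimony limit — it ignores substitution-state collisions
(slightly conservative) — and for an 857-bp locus with shallow divergence
it comfortably connects everything observed into one network.

The network itself is the union of all minimum spanning trees of the
step-distance graph restricted to edges within the limit (ties beyond one
deterministic, lexicographically tie-broken tree are kept and flagged as
alternative connections), with every k-step edge expanded through k−1
inferred intermediate nodes along the ascending-position mutational path
(an arbitrary but fixed choice, flagged in the output). This reproduces the
descriptive star-burst display; it is not a full cladogram-estimation
replica (connection order and loop resolution can differ from TCS), which
is acceptable for the descriptive use the network serves here.

## Synthetic data

* `simulate_star_expansion`: one random ancestral sequence; each lineage
  independently receives Poisson(θ*/2) mutations at distinct uniform sites
  (infinite-sites approximation), so the expected pairwise difference is
  θ*. This is the limiting genealogy of an extreme expansion and produces
  the high-h/low-π, strongly negative D/Fs, unimodal-mismatch regime.
* `simulate_two_pop_split`: two haploid demes of equal size with symmetric
  scaled migration and a clean split at t_split coalescent units
  (msprime), infinite-sites mutations mapped onto distinct columns of an
  857-bp alignment. Pilot settings in the tests exercise the
  weak-differentiation regime (fixation indices of order 0.01–0.1).
* `table2_fixture`: the published 37 × 4 frequency table reconstructed to
  exact integer counts, paired with deterministic synthetic 857-bp
  sequences in a shallow star (31 one-step and 5 two-step variants around
  the central haplotype; 41 polymorphic sites, 40 transitions and one
  transversion, matching the published polymorphism summary). The
  sequences are a labelled synthetic stand-in for the deposited GenBank
  haplotypes: every frequency-only statistic (h, F_ST, rarefaction,
  private haplotypes, the observer-accuracy table) matches the published
  values on this fixture, while distance-based statistics (Φ_ST, π,
  mismatch shape, H_RI) deliberately do not and are only validated on the
  real sequences when the user downloads them (see README). Passing tests
  on the fixture therefore demonstrate correctness of the frequency-based
  chain and of the machinery, not agreement of distance-based values with
  the study.

Sample sizes and Monte-Carlo settings in the tests are scaled to keep the
default suite fast (hundreds of permutations/simulations, 15–50 replicate
experiments); the statistical checks state their tolerances in terms of
the corresponding Monte-Carlo standard deviations.

## Defaults at a glance

| parameter | default | meaning |
|---|---|---|
| n_perm | 20,000 | AMOVA/pairwise permutations |
| n_boot | 20,000 | raggedness bootstrap replicates |
| neutrality sims | 20,000 | coalescent null samples for D/Fs p |
| Mantel perms | 9,999 | joint row/column permutations |
| resample reps | 10,000 | subsample-robustness replicates |
| subsample sizes | 150/100/60 | focal-population reduced sizes |
| α (pairwise family) | 0.05 | Holm family-wise level (initial α/k) |
| α (D), α (Fs) | 0.05, 0.02 | neutrality significance conventions |
| θ₁ cap | 9999 | sudden-expansion upper bound |
| parsimony confidence | 0.95 | network connection limit |

## Known limitations

* Statistical-parsimony limits and network layouts approximate, but do not
  bit-reproduce, TCS 1.21 (different tie-breaking and homoplasy model).
* The sudden-expansion τ̂ from a single locus is over-dispersed
  (see above); confidence statements about τ should come from the
  bootstrap, not the point estimate.
* π, D, Fs and H_RI values for the worked dataset require the real
  deposited sequences; the shipped fixture intentionally reproduces only
  the frequency structure and the polymorphism summary.
* Hierarchical (multi-group) AMOVA, exact tests of differentiation,
  median-joining networks and spatial-expansion mismatch models are out of
  scope.
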