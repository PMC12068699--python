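# Methods

## The model

Allele-specific read counts for one gene across a cohort are pairs
(Aᵢ, Nᵢ): reads assigned to an arbitrarily labelled A allele, out of all
allele-specifically mapped reads. Conditional on Nᵢ, Aᵢ is modelled as a
mixture of two *symmetric* beta-binomial distributions. A symmetric
beta-binomial is a binomial whose success probability is itself drawn
from Beta(α, α): its mean allele fraction is exactly ½ and the single
parameter α sets how far individual allele fractions stray from balance
(variance of the underlying beta is 1/(4(2α + 1))). Symmetry is a
modelling commitment, not a convenience: it makes the likelihood
invariant to which allele is labelled A, which removes any need for
phasing or for the over-expressed allele to be the same across
individuals — the properties that let the test reach variants far from
the gene.

The two components share nothing but the data: α₁ (relabelled after
fitting so α₁ ≥ α₂) describes the relatively balanced samples, α₂ the
imbalanced ones, and the mixing weight π is the probability a sample's
allele fraction comes from the balanced component. A candidate variant
is evaluated by splitting samples into heterozygotes and pooled
homozygotes at that variant and letting the weight differ between the
groups (π_het, π_hom). The null (shared π) is nested in this alternative
with one extra parameter, so the likelihood-ratio statistic is referred
to χ²(1). A per-genotype (three-class) parameterization with 2 df is
available (`aiqtl_test_groups`) but is not the default: the het/hom
contrast is the one a causal cis variant produces.

Assumptions worth stating: samples are independent given genotype;
counts for a gene come from one site per sample (multi-site input is
reduced by a max-coverage policy rather than summed, since summing
double-counts fragments and a haplotype-aware sum would need phasing);
and the chi-squared reference is asymptotic — see *Calibration* below.

## Fitting

All fits maximize the likelihood with Nelder–Mead in unconstrained
coordinates (log α₁, log α₂, logit π per group). Design choices:

- **Multi-start.** Six deterministic starting points spanning
  balanced/imbalanced component pairs (α ∈ {2, 20, 200}², π ∈
  {0.2, 0.5, 0.8}); `FitConfig.n_starts` truncates the list. The
  alternative model additionally always starts from the null optimum
  (π_hom = π_het = π̂₀) — this guarantees ℓ₁ ≥ ℓ₀ up to float precision —
  and the null is re-optimized from the alternative optimum with the
  single weight set to the group-size-weighted mean of (π̂_hom, π̂_het).
- **Bounds.** α is clipped to [1e-3, 1e6]; beyond these the pmf is
  numerically identical to its limits (point mass on extremes /
  Binomial(N, ½)). Boundary hits are reported, not errors: perfectly
  balanced data *should* drive α to the upper bound.
- **Tolerances.** Defaults: fatol 1e-8, xatol 1e-6, ≤ 2000 iterations
  per start. Large simulation experiments use a documented fast profile
  (`FAST_FIT`: 3 starts, fatol 1e-6, xatol 1e-4); side-by-side runs
  show test decisions unchanged at the third decimal of the type-I
  error.
- **Degenerate optima.** When the two components collapse (α₁ ≈ α₂ or
  both weights at a boundary) the LRT is still reported against χ²(1);
  no special-casing.
- **Determinism.** No randomness anywhere in fitting; identical input
  multisets give bit-identical results regardless of row order or
  allele labelling (observations are canonicalized to min(a, N−a) and
  deduplicated before optimization, and every floating-point expression
  is grouped symmetrically in a ↔ N−a).
- **Implementation.** The inner likelihood and the Nelder–Mead loop are
  compiled with numba when available (identical algorithm and
  termination rule to the scipy implementation, which remains as the
  fallback path and as a cross-check in tests).

Read filters: observations need ≥ 2 allele-mapped reads (`min_reads`),
pooled fits ≥ 20 observations, each genotype group ≥ 10 (`min_group_n`,
a stability choice; both are configurable). The same read filter is
applied to per-sample α fitting for uniformity.

## Simulation designs

Negative binomials are parameterized by (mean, size) with variance
mean + mean²/size; size 5 is heavily overdispersed, size → ∞ Poisson.
The default total read depth per sample is 30 (a realistic median for
allele-specifically mapped reads of one gene); the default cohort is
670 individuals with Hardy–Weinberg genotype classes at the stated MAF.

1. **Two independent negative-binomial haplotypes** (`two_negbin`):
   each haplotype's reads drawn independently; in heterozygotes the two
   means differ by a fold-change (1.2–1.5; 1 = null), normalized so the
   expected total is unchanged; the elevated haplotype is random per
   individual. This design deliberately does *not* share the model's
   structure (no conditioning on the total), probing misspecification.
2. **Negative-binomial total + symmetric beta-binomial split**
   (`negbin_sbb`): the model-matched design; heterozygotes use α_het,
   homozygotes α_hom (defaults 100/100 = null; power runs lower α_het).
3. **Trans-eQTL** (`trans`): both haplotypes' means scale with the
   alternative-allele dosage (×1.5 per allele, log-additive, recorded
   in the replicate metadata), the split carries no genotype signal.
   Expression then *correlates* with genotype while imbalance does not —
   the scenario in which depth-sensitive tests produce false cis calls.

Randomness: one integer seed per experiment; each replicate uses a
substream derived from (seed, replicate index), so tables are
bit-reproducible.

What these simulations do not emulate: mapping bias toward the
reference allele, correlated multi-gene structure, LD between the
tested variant and a causal one, imprinting/random monoallelic
expression in specific genes, and sample-level covariate structure.
Passing the suite therefore demonstrates the statistical behaviour of
the test under its stated sampling assumptions, not robustness to
alignment artefacts.

## Calibration of the LRT

Under all three null designs at 1,000 replicates the type-I error at
0.05 lands inside the binomial band [0.037, 0.065] and the
quantile-quantile slope against χ²(1) (central 99% of quantiles) inside
[0.9, 1.1]. Tail calibration — P(p < t) = t at t ∈ {0.01, 0.05, 0.1} —
holds within 3σ binomial bands for every design. The *full-CDF* shape
of the statistic deviates mildly from χ²(1) in mid-quantiles (a
Kolmogorov–Smirnov statistic of ~0.05–0.08 at 1,000 replicates): under
the null the two-component mixture often collapses, the weight contrast
is then weakly identified, and the chi-squared reference is only an
approximation away from the tail. This is a property of the statistic,
not of the optimizer (it is unchanged under much tighter tolerances),
and it does not affect decisions at any working significance level.

## Comparators

- `binomial_method`: per-sample two-sided exact binomial test against
  ½ (level 0.05 by default), then a Fisher exact test on the 2×2
  imbalanced × genotype table. Samples too shallow to ever reach
  significance (e.g. N = 4, minimal p = 0.125) are deliberately
  retained — that depth bias is the method's documented weakness, and
  with expression correlated to genotype (trans effects) it manifests
  as a grossly inflated false-positive rate.
- `threshold_method`: imbalanced iff the allelic proportion is strictly
  below 0.35 or strictly above 0.65; same group comparison.
- `wilcox_method`: rank-sum on |a/N − ½| between groups; exact p for
  combined n ≤ 20 (permutation when ties), tie-corrected normal
  approximation otherwise.
- `indep_bb_test`: group-specific vs shared symmetric beta-binomial
  dispersion, 1-df LRT. One monoallelic sample at very high coverage is
  enough to make this test significant while the mixture-weight test —
  in which that sample is a single observation with bounded influence
  on π — is not.

The group comparison for the classification methods defaults to
Fisher's exact test (chi-squared available via option).

## Distance-to-TSS regression

Detection (nominal p < 0.01 by default, Holm/BH available) is modelled
by logistic regression on |distance|/kb with separate slopes for
upstream and downstream variants (real data show asymmetric decay),
plus the power covariates: number of informative samples (≥ 2 reads),
median reads among them, MAF, and the eQTL association log₁₀ p. Fits
abort with diagnostics on constant response, perfect separation or rank
deficiency. Predicted curves are inverse-logit evaluations of the
fitted linear predictor; the logistic calibration identity (mean fitted
probability equals the observed detection rate) is used as the
correctness check, since prediction *at the covariate means* does not
equal the mean prediction for a nonlinear link.

## Parameter recovery and identifiability

π and the component dispersions are recovered to MAE(π) < 0.02 and
MAE(log α) ≲ 0.14 at n = 1000 — *provided read depth identifies the
balanced component*. A symmetric beta-binomial with α = 100 at depth 30
is numerically indistinguishable from Binomial(N, ½); the likelihood is
then flat in α₁ ∈ [100, ∞) and no optimizer can recover it. The
recovery harness therefore uses mean depth 300. Users should read
fitted α values above their typical N as "at least this balanced".

Per-sample α fitting is a 1-D bounded maximization of log α; with 2,000
genes at depth ~30 it recovers α = 20 within ±15%.

## Known limitations

- The χ²(1) reference is approximate off-tail (above); confidence
  intervals for π and α are not provided.
- The method tests association of *imbalance* with genotype: a variant
  in LD with the causal one is detected just the same, and a cis
  variant whose heterozygotes have too few allele-mapped reads is not.
- Multi-site counts are reduced, not combined; a phased-aware
  aggregation would use more information where phasing is reliable.
- Cell-type composition and other sample covariates are accepted as
  plain numeric tables for the correlation analyses; no deconvolution
  is performed.
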