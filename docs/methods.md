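# Methods

## Model and the variant-specific inflation factor

We consider the additive single-variant linear model
`y_i = β₀ + g_i β + ε_i` fitted on a pooled sample of M analysis groups
with group-intercept adjustment. Each group m contributes n_m
independent samples, a coded-allele frequency p_m for the variant, and a
phenotypic variance σ²_m assumed constant within the group (and, under
the strong null, independent of genotype). The Wald statistic divides
β̂ by its estimated standard error; under the homogeneous-variance model
that standard error uses a single pooled σ², whereas the true sampling
variance of β̂ is the sandwich form (WᵀW)⁻¹WᵀVW(WᵀW)⁻¹ with V the
diagonal of per-sample variances.

Instead of per-sample matrices we use their large-sample limits under
Hardy–Weinberg equilibrium within each group. The reduced design X is
3M × (M+1): a genotype column repeating (0, 1, 2) per group next to
group-intercept indicators. P is the diagonal of genotype-by-group cell
probabilities — the group's sample fraction n_m/n times the HWE
trinomial for its frequency — and V assigns σ²_m to the group's three
cells. With B = XᵀPX and A = XᵀPVX,

    λ_vs = [B⁻¹AB⁻¹]₁₁ / ([B⁻¹]₁₁ · tr(PV)),

where tr(PV) = Σ (n_m/n) σ²_m is the limit of the pooled single-variance
estimate under the null. λ_vs is the factor by which the
homogeneous-variance Wald chi-square of this variant is scaled in large
samples; it equals the genomic-control inflation that would be observed
if all variants shared this frequency configuration.

We implement the *unsquared* ratio of the two leading entries. Both
variance expressions are already on the variance (squared-error) scale,
and the chi-square statistic scales linearly with the
variance-misspecification ratio; the unsquared ratio is also what the
closed-form two-study derivation gives and what the simulations
reproduce on the λ_gc diagonal (see below).

Properties enforced by tests: λ_vs = 1 exactly when all groups share a
frequency, or all share a variance, or M = 1; invariance to rescaling
all σ²_m; invariance to flipping the coded allele in every group
simultaneously; monotone increase with the variance of the group
carrying the larger n·p(1−p) weight.

Closed form at M = 2 (used as an independent oracle, never in the
computation path): with weights w_m = n_m p_m (1 − p_m) and pooled
variance σ̄² = Σ (n_m/n) σ²_m,

    λ_vs = Σ w_m σ²_m / (σ̄² Σ w_m).

For M > 2 the tests compare against brute-force summation over
genotype-by-group cells with explicit matrix inversion.

### Conventions and numerics

* `p` is the coded (counted) allele frequency: HWE cells for dosages
  (0, 1, 2) are ((1−p)², 2p(1−p), p²). By the flip invariance, the
  orientation is a labelling convention only; frequencies must refer to
  the same physical allele in every group.
* Groups with p ∈ {0, 1} are allowed as long as at least one group is
  polymorphic: fixed groups contribute intercept information but no
  genotype information. If every group is fixed, the design limit is
  singular and an error is raised (condition-number threshold 1e12).
* Linear systems are solved directly; no explicit inverses are formed.
* Categories: Deflated if λ_vs < 0.99, Inflated if λ_vs > 1.01,
  Approx-none otherwise; boundary values are Approx-none (the open
  interval defines the central category). These thresholds are
  convention, not inference; the MAF-tabulation uses a finer reporting
  grid ((0,0.9], …, (1.1,∞)).

## Association models

**Homogeneous model** — OLS with group intercepts and covariates; the
single residual variance for Wald standard errors is the standard
df-corrected RSS/(n−p). Per-group *empirical variances* are the
uncorrected within-group means of squared residuals (1/n_m Σ ε̂²); this
estimator feeds both the FGLS reweighting and the per-replicate λ_vs
evaluation, and at GWAS sample sizes the df correction is immaterial.

**Stratified-variance model** — feasible generalized least squares:
initialize at the homogeneous fit, then alternate (i) per-group
empirical variances of the raw residuals and (ii) WLS with per-sample
weights 1/σ̂²_group, until the maximum relative change in any group
variance is below 1e-8 (default) or 50 iterations. The profiled
Gaussian objective Σ n_m log σ̂²_m is non-increasing across iterations
(tested). Non-convergence and collapsing group variances are reported,
not silently accepted. The mean coefficients and variances are estimated
by alternation rather than jointly; at convergence this is the same
fixed point.

**Wald test** — re-runs the chosen fitting procedure with the variant in
the mean model; chi2 = (β̂/se)², p from the χ²(1) upper tail. For the
stratified model, standard errors come from the weighted normal
equations with the usual finite-sample scale (weighted RSS/(n−p), which
is ≈1 by construction of the weights). Score tests would be
asymptotically equivalent under the null; Wald is used because it is
what the inflation-factor derivation describes.

**Two-stage rank-normalization** — fit the covariate-only model,
rank-based inverse-normal transform of its residuals with Blom offsets
((r − 3/8)/(n + 1/4), ties by average rank), then use the transformed
values as the trait in downstream fits. In the original mixed-model
workflow the null model includes a genetic-relatedness variance
component; this package's samples are independent, so the stage-1 model
is the fixed-effects analogue.

**Per-group meta-analysis** — each group fitted separately (complete
stratification: its own intercept, covariate effects and residual
variance), effects combined with inverse-variance weights; groups where
the variant is monomorphic are skipped and reported. Degenerate standard
errors or zero informative groups raise errors.

## Null simulations

The generator reproduces the two-study null design used to validate
λ_vs. Fixed across all settings: study intercepts 1 and 2, PC effect 1,
study-1 PC mean μ₁ = 2 with μ₂ = −n₁μ₁/n₂ balancing the pooled
*expected* mean to zero (the pooled sample mean is checked ≈ 0; the
distinction from balancing realized means vanishes asymptotically).
Varied over the canonical grid: n₁, n₂ ∈ {1000, 5000}; σ²₁, σ²₂,
σ²_g ∈ {1, 2}; MAFs p₁, p₂ ∈ {0.01, 0.05, 0.5}; and the error law —
ε ~ N(0, σ²_study + σ²_g) ("constant") or N(0, σ²_study + θ²σ²_g)
("pc_scaled", genetic variance driven by the PC so total variances
differ even at equal variance components). That is 2·2·2·2·2·3·3·2 =
576 settings. Genotypes are i.i.d. Binomial(2, p_study) and never enter
the mean model (strict null).

Per setting, each replicate redraws PC, genotypes and trait; both models
are fit with the genotype included; λ_gc per model is the median Wald
chi-square over replicates divided by the χ²(1) median (0.4549…,
computed from the distribution function, not hard-coded). λ_vs is
evaluated per replicate from observed study allele frequencies and
estimated variances — both the homogeneous-fit empirical variances and
the stratified-fit variances — and averaged; the two estimates agree to
well under 2% at the grid sample sizes (tested). Pooled-monomorphic
draws are redrawn within the replicate (counted and logged) so every
replicate contributes a testable variant.

Reproducibility: one root seed per setting; replicate streams are
spawned from a `numpy` SeedSequence so any single replicate can be
re-materialized independently of chunking (`replicate_table`).

Implementation note: the 10,000-replicate runs use a vectorized batched
normal-equation kernel (per-group cross-products, batched 4×4 solves,
FGLS iteration in coefficient space). Tests pin the kernel to the
statsmodels-backed single-replicate path to ~1e-9 relative agreement, so
the fast path is the same estimator, not an approximation.

### What the generator does and does not emulate

It reproduces frequency and variance stratification between independent
studies with a single confounding PC — the mechanism the inflation
factor quantifies. It does not include genetic relatedness (GRM-based
mixed models), covariate-dependent allele frequencies beyond the group
structure, genotyping error, or non-Gaussian traits. Passing the
simulation checks therefore demonstrates calibration of the variance
machinery under the stated mechanism, not robustness of a full WGS
analysis pipeline; in real mixed-model analyses the stratified residual
variance is an approximation when the *genetic* variance also differs by
group.

## Diagnostics

λ_gc of a variant set is median(chi2)/median(χ²₁). Its null sampling
band simulates n_sets independent sets of n_stats χ²(1) draws (defaults
10,000 stats × 1,000 sets) and takes the 2.5%/97.5% quantiles of their
λ_gc values; both quantiles are configurable. QQ series use the
(i − 0.5)/k plotting position within each λ_vs category plus an "All"
series; concatenating category series reproduces "All" exactly (tested).
The masking phenomenon — a mixture of predicted-inflated and
predicted-deflated variants whose pooled λ_gc looks null while the
category series separate — is reproduced on synthetic variant sets built
from λ_vs itself. Rendering plots is optional and untested; the QQ data
table is the canonical artifact.

## Problem sizes used in validation

The scaled-down diagonal validation uses twelve variance-stratified grid
settings at n₁ = n₂ = 1000 with 10,000 replicates each — enough that the
Monte-Carlo half-width of λ_gc (≈0.047 from the null band) cleanly
separates the inflated (λ_vs up to 1.19) and deflated (down to 0.81)
regimes, while one full run stays under a minute per setting on a single
core. The full 576-setting study is exposed through the CLI as a
long-running option rather than a test.

## Known limitations

* λ_vs assumes HWE within groups, no covariate effects inside the limit,
  and independent observations; with a GRM it is only approximate.
* The stratified-variance model corrects residual-variance
  heterogeneity; heterogeneous *genetic* variance requires complete
  stratification plus meta-analysis (supported here only under
  between-group independence).
* VCF frequency extraction handles biallelic records only; multiallelic
  records are skipped and counted.
* Rare-variant set tests are out of scope.
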