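# varstrat

Variance-stratification diagnostics for pooled multi-study genetic
association analysis.

## The problem

Large sequencing consortia pool samples from many studies and
race/ethnic groups into a single linear-regression GWAS. These "analysis
groups" often differ both in phenotypic variance (different
environments, measurement protocols, ancestry-related genetic variance)
and in allele frequencies. The sampling variance of a variant's effect
estimate under heteroscedasticity is

    var(β̂) = (Σᵢ gᵢ²)⁻² Σᵢ gᵢ² σᵢ²,

so a variant that is more common in a high-variance group has its true
sampling variance dominated by that group's σ² — while the default
homogeneous-variance model divides by a single pooled σ². The resulting
Wald statistic is inflated or deflated **per variant**, in a way that
depends on that variant's frequency pattern across groups. Crucially,
inflated and deflated variants can cancel in a genome-wide QQ plot,
making a miscalibrated analysis look clean ("masking").

## What the package computes

* **`varstrat.inflation`** — the variant-specific inflation factor
  λ_vs from group-level summaries (nₘ, pₘ, σ²ₘ) via the Hardy–Weinberg
  large-sample limit of the group-intercept design: with
  B = XᵀPX and A = XᵀPVX,

      λ_vs = [B⁻¹AB⁻¹]₁₁ / ([B⁻¹]₁₁ · tr(PV)),

  the ratio of the true (heterogeneous) to the assumed (homogeneous)
  sampling variance of the genotype coefficient. λ_vs = 1 exactly when
  all groups share a frequency or a variance; λ_vs > 1 predicts an
  inflated Wald chi-square for that variant, λ_vs < 1 a deflated one.
  Variants are categorized Deflated (< 0.99) / Approx-none / Inflated
  (> 1.01).
* **`varstrat.models`** — the homogeneous (OLS) and stratified-variance
  (iterated feasible GLS, one residual variance per group) association
  models, Wald tests, two-stage rank-normalization of the trait, and
  per-group analysis with inverse-variance fixed-effects meta-analysis.
* **`varstrat.simulation`** — two-study null simulations over the
  canonical 576-setting grid (n ∈ {1000, 5000}, σ², σ²_g ∈ {1, 2},
  MAF ∈ {0.01, 0.05, 0.5}, constant or PC-scaled genetic variance),
  comparing observed genomic-control inflation λ_gc against mean
  estimated λ_vs with 10,000 replicates per setting.
* **`varstrat.diagnostics`** — λ_gc over variant sets, its null
  sampling band, category-stratified QQ series, and the MAF × λ_vs
  contingency summary.
* **`varstrat.io` / CLI** — TSV schemas, per-group ALT-allele
  frequencies from a VCF plus sample-group map (pooled MAC ≥ 20 filter),
  and the `varstrat` command with subcommands `lambda`, `freqs`,
  `simulate`, `null-gc`, `qq`.

## Worked example

Three variants analysed across two analysis groups of 3000 samples each,
with phenotypic variances 2.2 and 1.0:

```python
import pandas as pd
from varstrat import GroupSummary, lambda_vs_table

groups = [GroupSummary("cohortA", 3000, 0.5, 2.2),
          GroupSummary("cohortB", 3000, 0.5, 1.0)]
freqs = pd.DataFrame({
    "variant_id": ["1:12345:A:G", "2:9876:C:T", "7:555:G:A"],
    "cohortA": [0.25, 0.02, 0.40],
    "cohortB": [0.25, 0.30, 0.01],
})
print(lambda_vs_table(groups, freqs).to_string(index=False))
```

```
 variant_id  lambda_vs   category
1:12345:A:G   1.000000 ApproxNone
 2:9876:C:T   0.689024   Deflated
  7:555:G:A   1.345288   Inflated
```

The first variant has the same frequency in both groups, so the pooled
variance happens to weight the groups correctly and λ_vs = 1. The second
is common mainly in the *low*-variance group: the homogeneous model
*over*-states its sampling variance, deflating its test statistic
(expected chi-square ~0.69× nominal — lost power). The third is common
mainly in the *high*-variance group and its test is inflated ~1.35×
(excess type I error).

The simulation module confirms the prediction; one stratified grid
setting (n₁ = n₂ = 1000, σ² = 2 vs 1, σ²_g = 1, MAF 0.01 vs 0.5,
10,000 null replicates):

```python
from varstrat import SimSetting, run_setting
r = run_setting(SimSetting(1000, 1000, 2.0, 1.0, 1.0, 0.01, 0.5, "constant"),
                n_reps=10000, seed=7)
print(r.lambda_gc_homogeneous, r.lambda_gc_stratified, r.mean_lambda_vs_empirical)
```

```
0.8110294748799848 1.0198209600442905 0.8151852631387347
```

The homogeneous model's observed inflation (0.811) matches the mean
estimated λ_vs (0.815), while the stratified-variance model is
calibrated (1.020, inside the null sampling band for 10,000 statistics).

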