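# Methods

## Problem and model

A continuous diagnostic biomarker is measured on `m` cases and `n`
controls. The discrimination target is `AUC = Pr(Y < X)` with `X` a random
case value and `Y` a random control value (cases-high orientation; values
below 0.5 are reported as-is, never flipped). Within-subject measurement
error — assay noise, technician and temporal variation, short-term
biologic variability — attenuates the observed AUC toward 0.5, so the
uncorrected estimate understates the marker's discriminating ability and
its confidence interval can miss the error-free AUC almost always when the
signal is strong.

The correction implemented here avoids any normality assumption on the raw
marker. Write `F_X`, `F_Y` for the true (error-free) distribution
functions and `H(z) = Φ⁻¹{F(z)}` for the probit transform, which maps any
continuous marker to an exactly standard-normal scale and depends on the
data only through ranks. The probit-shift model assumes

    Φ⁻¹{F_Y(z)} = Φ⁻¹{F_X(z)} + μ,

i.e. a pure location shift μ between groups *after* probit transformation
(a nonparametric analogue of the binormal ROC model; it holds exactly
whenever some monotone transform makes both groups normal with equal
variances). A first-order expansion of the AUC integral gives
`AUC_true ≈ Φ(μ/√2)`.

Measurement error is modeled as additive on the probit scale:
`H_obs = H_true + e`, `e ~ N(0, σ²_e)` independently per group. The
reliability of a single measurement on that scale is the one-way
intraclass correlation `ICC = 1/(1 + σ²_e)`, and propagating the error
through the same expansion yields the correction

    AUC_true ≈ Φ( Φ⁻¹(AUC_obs) · b ),    b = √((1/ICC_X + 1/ICC_Y)/2).

`b ≥ 1` whenever there is any error, so the correction always moves the
AUC away from 0.5, by symmetry the same way on both sides of 0.5. With
equal ICCs the formula coincides exactly with the normal-theory Faraggi
correction at `θ² = 1/ICC − 1`; this identity is used as a cross-check in
the tests.

## Estimation pipeline

1. **Observed AUC.** Mann-Whitney estimator on the designated *primary*
   measurement per subject (default replicate 1; configurable).
   Replicates never enter the AUC itself — they would induce
   within-subject dependence — only the reliability estimates.
   Variance: DeLong structural components by default (the
   Hanley–McNeil exponential approximation is selectable); Wald CI on the
   AUC scale truncated to [0,1], with a logit-scale option for small
   samples. Degenerate inputs (constant pooled data, perfect separation)
   produce a zero SE with an explicit `degenerate` flag.
2. **Reliability.** Within each group, every replicate column (all the
   group's replicate-r values) is transformed to normal scores as one
   batch — each replicate gets its own probit scale, so systematic
   level differences between collections do not masquerade as noise —
   and the one-way ANOVA ICC is computed from the transformed table.
   Unbalanced designs use the effective replicate count
   `k₀ = (N − Σk_i²/N)/(s−1)`; subjects with a single measurement are
   excluded from the ANOVA (they still contribute to the AUC).
3. **Correction and CI.** `a = Φ⁻¹(AUC_obs)`, `b` as above, and a
   first-order delta method for `se(a·b)`:

       se² = b²·var(a) + a²·var(b),
       var(a) = var(AUC_obs)/φ(a)²,
       var(b) = Σ_g var(ICC_g) / (16 b² ICC_g⁴),

   treating the AUC and the two ICCs as independent (the AUC uses only the
   primary replicate, the ICCs mostly within-subject contrasts; the
   residual correlation is ignored). `var(ICC)` is Fisher's large-sample
   approximation `2(1−ρ)²(1+(k−1)ρ)²/(k(k−1)(s−1))` with `k = k₀`; a
   subject-level bootstrap SE (seeded, default B = 1000) is provided as an
   alternative and serves as the test oracle — on a fixed simulated
   dataset the delta SE agrees with a 2000-replicate subject bootstrap
   within a few percent. The CI is `Φ(a·b ∓ z₁₋α/₂ se)`, default
   α = 0.05 (z = 1.959964).

**Reiser comparison method.** Per group, one-way ANOVA on the *raw* scale
gives error variance `MSW` and true variance `(MSB − MSW)/k₀`; then
`δ̂ = (X̄ − Ȳ)/√(σ̂²_X,true + σ̂²_Y,true)` and `AUC = Φ(δ̂)`. Its delta-method
variance combines the variance of the mean of subject means with
chi-square large-sample variances of the mean squares, groups independent.
This method is correct under normality and serves as the benchmark the
probit-shift method is compared against under skewness.

## Numerical choices and edge cases

- **ECDF offset.** Normal scores use midranks with `r/(n+1)` (van der
  Waerden) by default; Blom's `(r−3/8)/(n+1/4)` is available. Both keep
  Φ⁻¹ finite; ties map to equal scores, mirroring the Mann-Whitney tie
  convention.
- **ICC floor.** The correction divides by the ICCs, and ANOVA
  estimates can reach 0 or go negative; the between-subject component is
  clamped at 0 and the ICC at 0.01, with a `clamped` flag that propagates
  a warning into any downstream CI (such intervals are unreliable).
- **Boundary AUC.** A perfectly separated sample has `AUC_obs = 1`; it is
  clipped to `1 − 1/(2mn)` (symmetrically at 0) before Φ⁻¹, with a
  warning.
- **Zero total variance** in a replicate table (all values identical) is
  reported as ICC = 1 (perfect agreement) rather than 0/0.

## Simulation harness

Three generating models, all with `m` cases, `n` controls, `k` replicates
sharing the subject's true value:

| Model | true values | errors (additive) | defaults |
|---|---|---|---|
| I | `N(μ_g, σ²_true)` | `N(0, σ²_err)` | σ²_true = 1, σ²_err = 0.5 |
| II | `exp N(λ+μ_g, σ²_true)` | `N(0, σ²_err)` | all variances 1, λ = 0 |
| III | `exp N(λ+μ_g, σ²_true)` | `exp N(0, σ²_err)` | all variances 1, λ = 0 |

Model III errors are strictly positive with mean `e^{σ²/2}`; they are
deliberately not mean-centered — the lognormal error model is implemented
as written. The analytic true AUC is `Φ((μ_X−μ_Y)/√(σ²_X,true+σ²_Y,true))`
in every model (for II/III the location shift acts on the log scale and
`exp` preserves ranks). Default study conditions: `m = n = 100`, `k = 2`,
`μ_Y = 0`, `μ_X ∈ {0.25, 0.5, 1}`.

`evaluate` performs `n_runs` runs of `n_datasets` datasets; per dataset
each estimator (uncorrected MW, Reiser, probit-shift) yields an estimate
and CI; per run bias, MSE, and coverage against the analytic true AUC are
averaged; across runs the report carries means with normal-approximation
95% intervals (`mean ± 1.96·sd/√n_runs`). Every dataset's generator is
seeded from `(base_seed, run, dataset)` via `SeedSequence`, so reports are
bit-reproducible. Estimator failures are excluded and counted; more than
1% in a run aborts. The per-dataset analysis has a vectorized array path
that the tests verify is numerically identical to the long-format dataset
path.

**Problem sizes.** The package's standard verification protocol uses 10
runs of 1000 datasets per parameter cell (tolerance bands widened by the
across-run Monte-Carlo error this implies) and 500-dataset cells for the
parameter-recovery checks; at these sizes the full study runs in well
under a minute per model.

## What the simulations do and do not show

The generators reproduce the study conditions: moderate samples, two
replicates, error-to-signal ratios 0.5–1, and skewness via lognormality.
Measured behavior at μ_X = 1: the uncorrected AUC is biased toward 0.5 in
every model (≈ −0.04 here) with CI coverage far below nominal; the Reiser
correction is essentially unbiased under normality (Model I) but badly
biased (≈ −0.07) and undercovering (≈ 46%) under lognormality; the
probit-shift correction stays within Monte-Carlo error of the true AUC in
all nine model × shift cells with coverage ≈ 94–95%.

Real data differ in ways the generators do not emulate: replicates
separated in time can violate the stable-true-value assumption (the ICC
then mixes error with biologic drift and the correction overshoots);
markers with detection limits or heavy discreteness break the continuity
assumption behind the probit transform; the probit-shift model itself
assumes equal probit-scale variances between groups (an unequal-variance
extension `H_Y = c₁H_X + c₂` is out of scope). Passing simulations
therefore validate the estimators under the stated models, not the model
assumptions for any particular biomarker.

## Known limitations

- First-order Taylor approximations underlie both the correction and its
  CI; with very large error (`θ² > 1`) the correction remains nearly
  unbiased but its intervals become conservative.
- The delta method ignores the small correlation between the observed AUC
  and the estimated ICCs (both computed from the same subjects); the
  bootstrap comparison bounds the effect at the percent level for
  m = n = 100.
- ICCs clamped at the floor (no detectable between-subject variance) make
  the corrected AUC essentially unidentified; results carry warnings and
  should not be interpreted beyond "the marker is unreliable".
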