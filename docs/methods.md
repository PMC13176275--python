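# Methods

## The experimental model

The package targets a balanced two-factor split-plot pot experiment:
temperature regime (default levels `Tamb`, `T1`, `T2`) randomized to main
plots, water regime (`WW` well-watered, `WS` water stress, `SS` salt
stress) to subplots within each main plot, with `r` replicates (default
10, so 3 × 3 × 10 = 90 pots and 30 main plots). Treatments are named the
way the field names them: `WW` is the ambient well-watered control, warmed
well-watered pots are `T1`/`T2`, and combined stresses are `WS(T1)`,
`SS(T2)`, etc.

Every analysis stage assumes the observation model

```
y_ijk = μ + α_i + β_j + (αβ)_ij + m_ik + e_ijk
```

with temperature effects α, water effects β, interaction (αβ) in
sum-to-zero coding, a main-plot random effect `m_ik` shared by the three
subplots of a (temperature, replicate) pair, and a subplot residual
`e_ijk`. Gaussian `m` and `e` are an assumption, not a measurement: no
distributional model of pot-level variation is implied by the design
itself.

## Trait derivation

Raw per-pot measurements are shoot and root dry weight (g), total water
applied (L), N concentration of the composite shoot+root sample
(mg N g⁻¹), atom% ¹⁵N, and δ¹³C (‰ vs PDB). Constants, all configurable
through `IsotopeConstants`:

| constant | default | unit | meaning |
|---|---|---|---|
| natural abundance | 0.3663 | atom% ¹⁵N | baseline of unlabelled N |
| fertilizer enrichment | 10 | atom% ¹⁵N | label of the applied N |
| `f` (recovery divisor) | 0.0403 | g N pot⁻¹ | fertilizer N applied |
| δ¹³C of air | −8.15 | ‰ | source CO₂ signature |

Two genuinely open choices are exposed as switches and defaulted
deliberately:

- **Biomass basis.** N uptake, WUE and NUE use shoot+root by default,
  because the N analysis is performed on a composite whole-plant sample;
  `biomass="shoot"` restricts to shoot only.
- **Recovery divisor.** `%¹⁵Nrec` is conventionally expressed per unit
  fertilizer *N*; `f` therefore defaults to the fertilizer-N mass per pot
  (190 mg ammonium sulfate × 0.212 N = 0.0403 g). Setting `fert_amount_g`
  to the product mass gives a product-basis percentage instead.

Nine traits enter the downstream analyses: shoot, root, water
consumption, WUE, N concentration, N uptake, %¹⁵N recovery, NUE, and
Δ¹³C. NUE on the composite-sample basis equals 1000/[N] identically —
the traits are deliberately the field's standard panel, redundancy
included; the CDA guards against numerical singularity with a
condition-number check rather than by silently dropping traits.

## Bootstrap effect sizes (BCa)

Each contrast resamples its two groups independently with replacement at
their own sizes (the pot is the resampling unit; main-plot structure is
ignored at this stage, matching standard two-group estimation
statistics). Implementation choices that matter for bit-reproducibility:

- z₀ counts bootstrap statistics tied with the observed value as half
  below (continuity correction).
- Acceleration uses the leave-one-out jackknife across all observations
  of both groups, each removed from its own group.
- Endpoints are linear-interpolated quantiles of the bootstrap
  distribution at the BCa-adjusted levels; adjusted levels outside (0, 1)
  are clamped to the extreme order statistic and flagged (`clamped`).
- Every (trait, contrast) pair draws from an RNG substream keyed by
  (seed, trait, treatment, baseline), so adding or reordering contrasts
  never changes another contrast's interval.

Default `n_boot` is 5000; the calibration study in the test suite and
acceptance script measures the empirical coverage of these intervals for
Gaussian groups of n = 10. BCa intervals are known to undercover at such
small per-group sizes (the bootstrap plug-in variance is biased by
(n−1)/n and the calibration is normal rather than t); the measured
coverage agrees with scipy's independent BCa implementation on identical
data, so the deviation from the nominal 95% reflects the method at this
sample size, not this implementation.

## Additivity index

For stresses i and j, with all effect sizes against the same control:
`AI = ES_ij − (ES_i + ES_j)`. The four groups are resampled jointly —
one AI\* per iteration — which preserves the index's sampling
distribution (resampling contrasts separately and differencing stored
bootstrap draws would not). The CI is bias-corrected percentile (z₀
only) by default; `method="bca"` adds acceleration from a grouped
leave-one-pot-out jackknife. A jackknife-accelerated four-group
functional is unusual enough that the plain bias-corrected interval is
the default.

The sign-flip p-value is `p = 2·min(#{AI* ≤ 0}+1, #{AI* ≥ 0}+1)/(B+1)`,
never exactly zero. Classification: *additive* iff the CI contains 0;
otherwise the sign of AI is compared with the expected additive effect
`S = ES_i + ES_j` — same sign means the combination overshoots the
additive expectation (*synergistic*), opposite sign undershoots it
(*antagonistic*); if S = 0 the label is *non-additive-unsigned*. The
heatmap matrix reports `100·AI/mean(control)` per combo × trait with a
mark where p < 0.05; cells with a zero control mean are NaN, not
infinity. No multiplicity correction is applied across the heatmap's
cells; users comparing 36 cells should interpret isolated marks
accordingly.

The same small-sample caveat as for BCa applies: at n = 10 per group the
bias-corrected interval's false-positive (non-additive) rate measured on
exactly additive scenarios runs a few points above the nominal 5%;
the calibration is part of the acceptance script so the current figure is
always recomputable.

## Split-plot ANOVA

Balanced-design moment decomposition (no design-matrix fitting):
temperature SS from temperature means, among-main-plots-within-temperature
as the whole-plot error (df = t(r−1) in the default, completely
randomized form; `blocks=True` adds a replicate block main effect and
leaves df = (t−1)(r−1) for the main-plot error), water and interaction
from cell means, residual by subtraction. F(temperature) uses the
main-plot error mean square; F(water) and F(interaction) use the subplot
residual. Unbalanced tables are rejected outright — there is no
approximate fallback, because Type-I/III sums of squares in unbalanced
split plots are a different method, not a tolerance.

Diagnostics: Shapiro–Wilk on the subplot residuals
`y − cell mean − (main-plot mean − temperature mean)` and Brown–Forsythe
(median-centered Levene) across the t×w treatment groups. Transformations
(log, sqrt) are applied only on request — a refit on the transformed
scale is attached to the report when assumptions fail — never
automatically.

## Canonical discriminant analysis

Between-group scatter **B** (group-size weighted) against pooled
within-group scatter **W**; the generalized symmetric eigenproblem
`B v = λ W v` is solved with `scipy.linalg.eigh`, and coefficients are
rescaled so canonical scores have unit pooled within-group variance.
Traits enter unstandardized: the within-scatter whitening makes the
analysis invariant to affine rescaling of the inputs, so standardization
would change nothing but the raw coefficients. Structure loadings are
total-sample correlations between each trait and each canonical score
(the convention of the common discriminant-analysis reporting tools);
signs are fixed so the largest-|loading| trait of each variable loads
positively, making seeded runs comparable. Percent variance is
λ_k / Σλ over the retained min(p, g−1) variables; tiny negative
eigenvalues from floating-point are clipped to zero.

Mahalanobis squared distance uses the pooled covariance
`S = W/(N−g)` from *all* groups; per pair,
`T² = (n_g n_h/(n_g+n_h)) D²` and `F = T²(ν−p+1)/(νp)` with ν = N−g on
(p, ν−p+1) degrees of freedom. With only two groups this reduces to the
classical two-sample Hotelling test. A condition number above 1e12 on
**W** aborts with a message naming the condition number; observations
missing any trait are removed listwise with a logged count.

## Synthetic generator

The generator is the package's study-condition definition, not a demo.
Default cell means emulate a maize warming × water/salt-stress pot
experiment: WW shoot ≈ 1.3 g and root ≈ 0.7 g per pot, salt stress
roughly halving biomass and water use, water stress cutting shoot growth
~20% and fertilizer recovery ~40%, warming raising water consumption and
eroding WUE; atom% ¹⁵N cell means are back-calculated so that fertilizer
recovery lands near 9% of applied N in the control, and δ¹³C means
correspond to Δ¹³C ≈ 5.8‰. Dispersions (per-trait main-plot and residual
SDs) are set so that 95% CIs at n = 10 have widths typical of such
experiments (e.g. ±0.12 g for shoot contrasts).

Admissibility (positive masses, atom% between natural abundance and the
fertilizer label) is enforced by re-drawing the subplot residual — up to
1000 attempts per value, then a hard error — rather than truncating,
which would bias cell means. Each measurement has its own RNG substream
keyed by (seed, trait name): adding a trait never perturbs the draws of
another, and identical (config, seed) reproduce tables bit-identically.

What the generator does **not** emulate: cross-trait correlation beyond
what the trait equations induce (raw measurements are drawn
independently), non-Gaussian or heteroscedastic pot noise, temporal
dynamics of soil moisture or growth, and measurement error structure of
the mass spectrometer. Passing tests therefore demonstrate correctness of
the statistical machinery under the declared model, not robustness to
real-data pathologies such as skewed residuals or correlated traits.

## Problem sizes

The test suite and acceptance script run the calibration studies at the
sizes the analyses are designed for: 10⁴ randomized formula checks;
1000 coverage experiments × 1000 resamples; 500 additivity type-I and 500
recovery/power experiments at n_boot = 500–1000; 2000 null ANOVA
simulations; and the full 90-pot, n_boot = 5000 pipeline run twice for
byte-identity. The complete suite runs in a few minutes on one CPU.

## Known limitations

- Bootstrap stages ignore the main-plot random effect; with a large
  main-plot variance component, contrasts that cross main plots inherit
  extra (unmodelled) correlation.
- Small-sample undercoverage of percentile-family bootstrap intervals at
  n = 10 per group, quantified above and in the calibration outputs.
- Fixed-effects-only ANOVA; no REML/mixed-model refit.
- CDA offers no classification or cross-validation; it is descriptive
  ordination plus distance testing.
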