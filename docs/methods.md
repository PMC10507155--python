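# Methods

## Model and hypothesis structure

For a two-way admixed individual, locus-specific ancestry at a marker is
the number of allele copies (0/1/2) inherited from a designated parental
population. Two conditionally independent pieces of evidence are
computed per variant:

* **Admixture mapping** — regression of the phenotype on the ancestry
  count, giving an effect `β_A` with Z score `Z_A`. A locus where the
  parental populations differ in trait-allele frequency shows an excess
  of the higher-frequency ancestry among trait-elevated individuals.
* **Structured association** — regression of the phenotype on genotype
  dosage *within* each ancestry stratum (homozygous-0, heterozygous,
  homozygous-2), pooled by inverse-variance meta-analysis into `Z_G|A`.
  Stratifying makes the genotype effect conditionally independent of the
  ancestry effect and is robust to the unknown mode of inheritance.

The joint test targets the intersection alternative (ancestry effect AND
association effect AND mutual directional consistency) with the
statistic `T = sign(f2 − f0) · Z_A · Z_G|A`, where `f0`, `f2` are
effect-allele frequencies in the homozygous strata. An association can
causally explain an ancestry effect only if the ancestry with more of
the effect allele is the one associated with the trait shift; that
configuration and only that configuration makes `T` positive, hence the
one-tailed test. Under the null (either Z score null), `T` is a product
of two independent standard normals and the frequency sign is
independent of both, so `p = P_prodnorm(X > T)`.

Assumptions: two ancestral strata (pairwise comparisons); allelic
substitution effects independent of ancestry background (testable via
the heterogeneity statistics); quantitative phenotype analyzed by linear
regression, though the statistic itself only consumes summary-level
Z scores and frequencies and is agnostic to how they were fitted.

## Product-normal numerics

Density `K₀(|x|)/π`; log-singular (integrable) at 0, so `pdf(0)` returns
`inf` by contract and normalization uses `∫₀^∞ K₀ = π/2`.

Survival function, two regimes split at `x = 8`:

* `0 ≤ x ≤ 8`: `sf = 1/2 − (1/π)∫₀ˣK₀`, with the Bessel integral in
  closed form via modified Struve functions,
  `∫₀ˣK₀ = (πx/2)[K₀L₋₁ + K₁L₀]` (machine precision; cancellation loss
  at the switch point is ~1e-12 relative).
* `x > 8`: exponent-scaled adaptive quadrature
  `sf = (e^{−x}/π)∫₀^∞ k0e(x+t)e^{−t}dt` with `k0e = eᵘK₀(u)`. The
  scaled integrand is O(1), so the route never underflows and a log-scale
  variant (`log_sf`) stays finite for arbitrarily deep tails (scan hits
  with `p < 1e-300`). Quadrature tolerance 1e-13 relative.

Negative arguments by symmetry `sf(−x) = 1 − sf(x)`. Quantiles by
bracketed root finding (Brent) on `log sf` over `[0, 800]`, covering
one-tailed p values down to the smallest positive double; the median
returns exactly 0. One unavoidable double-precision limit: for
`x ≲ −21`, `sf(x)` is `1 − tiny` and re-forming the complement loses
~5 significant digits, so the round-trip `quantile(sf(x)) = x` is exact
to 1e-6 only on `[−20, ∞)` and to ~1e-2 at −30; upper-tail quantiles
(the ones inference uses) are unaffected.

The exactly computed genome-wide critical value is
`quantile(5e-8) = 14.51497`. Chained through the benchmarking calculus
with unrounded intermediates this gives required `Z_G|A = 3.2860`
(two-sided `p = 1.016e-3`), fold `= 2.752`, and break-even ancestry
`p = 7.753e-3` at twin 5e-8 levels.

## Benchmarking calculus

All p↔Z maps use the two-sided convention `z = Φ⁻¹(1 − p/2)`, the only
convention consistent with the standard genome-wide correspondence
`5e-8 ↔ 5.45`. `required_assoc_z` divides the product-normal quantile by
the ancestry Z; `sample_size_fold` squares the ratio of the standard
genome-wide Z to the required Z (Z ∝ √n at fixed effect size);
`breakeven_ancestry_p` inverts the chain. Intermediates are never
rounded; display rounding happens only at the CLI.

## Meta-analysis

Fixed-effect pooling with weights `1/SE²` (the standard-error scheme):
`β̂ = Σwβ/Σw`, `SE = 1/√Σw`. Cochran's `Q = Σw(β − β̂)²` on `k − 1`
degrees of freedom, heterogeneity p from the upper χ² tail,
`I² = 100·max(0, (Q − df)/Q)` truncated at zero. Strata with missing
effects or nonpositive SEs are excluded from pooling and from df but
keep a `?` slot in the direction string, so its length always equals the
number of input strata. Random-effects pooling is out of scope.

## Regression layer

All models are ordinary least squares with fixed covariates (age, sex,
optional study indicators, optional genome-wide admixture proportion).
The synthetic cohorts are generated unrelated, so no genetic-relatedness
random effect is fitted; the covariate list is the extension point for
richer designs. Design matrices are explicitly rank-checked (collinear
covariates are an error, not a silent drop). Strata smaller than 30
individuals (configurable) or without genotype variance are omitted from
the stratified association with a warning — small strata produce
unstable SEs that corrupt the pooled Z. Conditional association adds the
conditioning variants' dosages as covariates in every stratum, the
covariate-adjustment realization of iterative conditioning. Stratum
allele frequencies are mean dosage / 2 within each homozygous stratum;
an empty stratum yields NaN and the joint-test record is flagged
degenerate rather than given an imputed sign, because the sign is
load-bearing. The genetic score is
`intercept + β_age·age + β_sex·sex + Σβⱼ·dosageⱼ` with explicit
effect-allele alignment (mismatched alleles flip dosage to `2 − d`).

## Simulation design

**Validity experiment.** One million triplets of independent standard
normals; statistic `sign(W)·Z₁·Z₂` (the sign variate models the
frequency differential, independent of both Z scores under the null);
rejection above the product-normal one-tailed critical value. With
10⁶ replicates the binomial standard error at α = 0.05 is 2.2e-4, so
calibration is asserted within ±6.5e-4 (3 SEs).

**Power surface.** The association Z is drawn `Normal(μ, 1)` for μ on a
grid while the realized ancestry Z is held fixed in {0,…,4}; effects are
independent with consistent (positive) frequency sign by construction.
Power is identically zero at `Z_A = 0` — the product cannot be nonzero
unless both scores are — and monotone in both arguments.

**Cohort generator.** Per individual, admixture proportion
`θ ~ Beta(8, 2)` (mean 0.8 of ancestry 2, the African-American average
for African ancestry); per locus, ancestry count `~ Binomial(2, θ)`;
each ancestry-2 allele copy carries the effect allele with probability
`freq_anc2` and each ancestry-0 copy with `freq_anc0`; phenotype
`= β_A·anc + β_G·dos + β_age·age + β_sex·sex + N(0, σ)`. Defaults are
the LPL-like configuration: `freq_anc2 = 0.429` vs `freq_anc0 = 0.689`
(the triglyceride-raising allele commoner on the European background),
`β_G = +0.1` per allele on the natural-log trait scale, `β_A = 0`
(ancestry effect fully mediated by the variant, matching the observation
that conditioning on the index variant extinguishes the ancestry
signal), `σ = 0.8` (a typical residual SD of log-transformed serum
triglycerides), age `N(50, 10²)` years with `β_age = 0.002`/year, sex
Bernoulli(1/2) with `β_sex = 0.1`.

What the generator does **not** emulate: ancestry-tract correlation
along the chromosome (loci are independent given θ — irrelevant to the
single-locus test but unrealistic for multi-locus admixture-scan
significance thresholds), linkage disequilibrium between variants,
relatedness and population substructure beyond a scalar θ, genotyping or
local-ancestry-inference error, and case-control ascertainment. Passing
tests therefore establish the statistic's calibration, power behavior
and sign logic, not robustness to those real-data complications.

End-to-end parameter-recovery checks run 30 replicate cohorts of 4,000
individuals with `β_G = 0.073` and a direct ancestry effect of −0.067,
chosen so both the marginal ancestry Z and the pooled association Z sit
near |4| — strong enough that the signed product should be positive in
essentially every replicate, small enough that estimation error is
visible. Simulation sizes throughout (10⁶ validity replicates, 10⁷
Monte-Carlo tail draws, 2×10⁴-replicate power cells) were fixed in
advance to make three-binomial-SE assertions decisive.

## Numerical and degenerate-input policy

* `sign(0) := 0`: an exact frequency tie gives statistic 0, p = 0.5,
  flagged degenerate — a tie carries no directional information and must
  never produce evidence. Likewise a zero Z score.
* Missing `f0`/`f2` or non-finite Z: the record is flagged degenerate
  with NaN statistic rather than dropped (scan output aligns 1:1 with
  input) and never silently assumed consistent.
* P values are reported with a log10 companion column; scans can exceed
  double underflow and the log column is the durable value.
* When only two-sided p values and effect signs are available upstream,
  Z scores should be reconstructed as `z = sign(β)·Φ⁻¹(1 − p/2)`,
  matching the package's two-sided convention.

## Known limitations

Two-way admixture only (the statistic is defined for pairwise ancestry
comparisons); fixed-effect OLS rather than mixed models (no GRM random
effect, no leave-one-chromosome-out correction); no local-ancestry
inference — ancestry counts are taken as known; the generator's
independence simplifications listed above.
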