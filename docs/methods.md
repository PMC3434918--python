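# Methods

## The experimental design being modelled

The unit of observation is a single greenhouse plant: one of six highly
inbred *Medicago truncatula* genotypes (three from a thyme-co-occurring
site — NA1021, NA216, NA632 — and three thyme-naive — A17, DZA012,
F20089-B), inoculated with one of two two-strain *Sinorhizobium meliloti*
mixes ("b", isolated where thyme grows; "g", thyme-naive) or left
uninoculated, grown on soil with or without carvacrol, five replicates per
cell: 6 × 3 × 2 × 5 = 180 plants.  Nodule count proxies rhizobium fitness;
fruit count proxies plant fitness.  Because both plant lines and mixes are
repeatable genetic entities, the 12 genotype × mix associations per soil
environment act as a "virtual reference population" over which broad-sense
genetic parameters are defined.

## Estimation model

Within one environment, associations are a single random factor in a
balanced one-way MANOVA on **y** = (nodule count, ln fruit).  Writing
H and E for the between-group and residual sum-of-cross-products matrices,
the expected mean cross-products under the balanced random-group model are
E[E/(g(k−1))] = Cov_E and E[H/(g−1)] = Cov_E + k·Cov_G, inverted to

- `Cov_E = E / (g(k−1))` — always positive semidefinite, so |r_E| ≤ 1;
- `Cov_G = (H/(g−1) − Cov_E) / k` — a moment estimate whose diagonal can go
  negative in finite samples.

Negative genetic variances are reported and flagged, and the corresponding
correlation is tagged *undefined* rather than truncated: clamping to zero
would shrink the jackknife spread and bias its SE downward.  The jackknife
uses the standard delete-one-group form with the (m−1)/m factor computed
over the m defined replicates; dropped (undefined) replicates are counted
in the diagnostics.  A strict mode is deliberately absent from the default
path so that stochastic simulation studies run to completion.

Trait order is fixed as (nodules, ln fruit) everywhere.  The fruit
transform defaults to ln(y+1) (uninoculated plants on carvacrol soil can
plausibly set zero fruit); a strict ln(y) policy is available and errors on
zeros.  One offset policy configures both the ANOVA and the correlation
pipeline, so the two analyses always see the same response.

The factorial ANOVA treats M, R and ST as crossed fixed factors, fitted by
OLS with a sequential decomposition; on the balanced designs this package
accepts, sequential and marginal sums of squares coincide, and unbalanced
input is refused outright (with the offending cells named) rather than
estimated.  Controls are excluded by default (R on 1 df, 96 error df on
120 plants); the include-control mode treats the uninoculated group as a
third rhizobium level (R on 2 df), which is the only mode in which a soil
main effect on plant fitness is expected to surface, since rhizobium-
deprived plants are hit hardest by carvacrol.  Post-hoc home/away
comparisons are pooled-variance two-sample t tests on plant-level values
(Welch available behind a flag).

Genotypic values per association are plain cell means; the major-axis line
through their bivariate scatter is the first principal axis of the 2×2
covariance of the means, with slope/intercept through the centroid.  An
exact eigenvalue tie (circularly symmetric cloud) and a vertical axis are
refused as degenerate rather than resolved arbitrarily.

## Synthetic-data generator

The generator mirrors the estimation model: per environment, one latent
bivariate genotypic value per association from Normal(μ + effects,
Cov_G[env]); per replicate, additive Normal(0, Cov_E) residual noise shared
across environments.  Nodules are rounded and truncated at zero; ln-fruit
is exponentiated then rounded.  Counts therefore follow a
latent-Gaussian-round model, not a Poisson family — the estimator is a
Gaussian moment method and, at means in the tens to hundreds, rounding
perturbs the moment structure negligibly (truncation at zero affects ~2% of
nodule draws at the default means).  `return_latent=True` exposes
pre-rounding values so moment-convergence tests are free of rounding bias.

### Calibration of the `study` preset (defaults, units)

| parameter | value | basis |
|---|---|---|
| residual SD, nodules | 44 | per-association SEM ≈ 19–20 at k = 5 |
| residual SD, ln fruit | 0.56 | per-association SEM ≈ 0.2–0.3 at k = 5 |
| residual correlation r_E | 0.08 | reported environmental correlations (0.07–0.08) |
| genetic SD, nodules | 30 | between-association/error mean-square ratio ≈ 4 |
| genetic SD, ln fruit | 0.6 | between-association/error mean-square ratio ≈ 6 |
| genetic correlation | 0.6 (carvacrol) / 0 (control) | the reported environment contrast, idealised |
| latent means (nodules, ln fruit) | (115, 3.0) control; (105, 3.0) carvacrol | mean nodule counts ~100, fruit ~20; small soil main effect among inoculated plants |
| home_effect | +25 nodules | home-genotype × home-mix × carvacrol cells; reproduces a detectable home-mix advantage for the thyme-site genotypes |
| control fruit penalty (ln scale) | 0.8, +0.7 extra on carvacrol | uninoculated plants set fewer fruit, most on carvacrol soil |
| seed | 0 | single `numpy` Generator drives all draws |

These defaults are the study conditions the package simulates; they were
fixed from the design constants and reported summary scales before any
calibration experiment was run, and are not adjusted per analysis.

### What the generator does and does not emulate

It reproduces the balanced factorial structure, the between- vs
within-association covariance decomposition per environment, count-valued
responses at the right scale, zero-nodule controls with a fruit penalty,
and a home-mix nodulation advantage.  It does **not** model: strain
competition inside a mix or nodule occupancy; overdispersed count noise;
spatial/block effects; or a cross-environment genetic correlation —
genotypic values are drawn independently per environment, so
genotype × soil interaction variance is maximal by construction and the
simulated M × ST / M × R × ST mean squares run hotter than a real
experiment with partially parallel reaction norms would show.  Passing
tests therefore demonstrate correctness of the estimators under the assumed
covariance structure, not robustness to features of real data the generator
omits.

## Estimator behaviour at the study's size

With g = 12 and k = 5 and the preset's signal-to-noise, 500-experiment
simulations (seeds fixed in `analysis/04_recovery.py` and the acceptance
script) give mean r̂_G ≈ 0.55 at a generative 0.6 and ≈ −0.01 at 0, with
across-experiment SDs ≈ 0.37 and ≈ 0.45 and mean jackknife SEs ≈ 1.1–1.25×
those SDs.  A handful of experiments per 500 (~2%) yield a negative moment
variance and an undefined r̂_G; they are excluded from the means with their
count reported.  Two consequences worth stating plainly: a single
experiment of this size estimates r_G with an SE of roughly 0.4, and the
probability that the higher-correlation environment also *shows* the higher
estimate in one paired experiment is only about 0.8.

## Numerical choices and degenerate inputs

- Balance is a hard precondition for the moment identities and the
  ANOVA decomposition; violations raise with offending cells listed.
- g < 2 or k < 2 makes one component inestimable and raises; the jackknife
  additionally requires g ≥ 3.
- H + E is conserved against the total corrected cross-products to
  ~1e-15 relative (asserted in tests on random data).
- Matrix symmetry tolerance 1e-10 relative; PSD tolerance allows
  eigenvalues down to −1e-10 × the spectral radius.
- Correlations from a PSD matrix are computed without clipping; values can
  exceed 1 in magnitude only for the (flagged, non-PSD) Cov_G case.
- All file outputs keep full float precision; console tables round to 2–3
  significant digits.

## Problem sizes used in tests and the acceptance script

Recovery and calibration runs use 500 simulated experiments (plus 200 for
the environment-contrast rate); convergence property tests use single
associations with k = 10⁴, and g up to 2×10³ at k = 5.  These sizes put
Monte-Carlo error well inside the asserted tolerances while keeping the
whole suite fast on one CPU.

## Known limitations

- Broad-sense only: with clonal lines and fixed mixes, genetic and
  non-additive/maternal components are confounded by design; no REML or
  Bayesian variance-component machinery is provided or intended.
- The moment r̂_G is a ratio estimator and mildly biased toward zero at
  g = 12 (≈ −0.05 at a true 0.6 under the preset).
- The two-trait (2×2) case is hard-wired; no >2-trait generalisation.
- Unbalanced data are rejected, not reweighted.
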