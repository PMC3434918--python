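# rhizocorr

Does the biotic environment change whether a mutualism's partners rise and
fall together?  In the legume–rhizobium symbiosis, the host plant
(*Medicago truncatula*) feeds nitrogen-fixing bacteria (*Sinorhizobium
meliloti*) housed in root nodules; a third species — thyme — leaches the
monoterpene carvacrol into the soil around both.  `rhizocorr` implements
the statistical machinery for a balanced G×G×E greenhouse design that asks
this question: 6 plant genotypes × (2 rhizobium strain mixes +
uninoculated control) × 2 soil treatments (carvacrol / control) × 5
replicates = 180 plants, with nodule count as the rhizobium fitness proxy
and fruit count as the plant fitness proxy.

It is written for quantitative geneticists and ecologists running (or
re-analysing) factorial partner-fitness experiments who need the full
chain: validated plant-level tables, a calibrated simulator, factorial
ANOVA, and the moment-based correlation estimator with resampling SEs.

## The estimator

Within one soil environment the g = 12 genotype × mix associations are a
single random factor in a balanced one-way MANOVA with the bivariate
response **y** = (nodule count, ln fruit).  With k = 5 replicates per
association, the between-association (**H**) and residual (**E**)
sum-of-cross-products matrices give method-of-moments components

    Cov_E = E / (g(k − 1)),        Cov_G = (H/(g − 1) − Cov_E) / k,

and the broad-sense genetic and environmental correlations

    r_G = Cov_G[1,2] / √(Cov_G[1,1]·Cov_G[2,2]),   r_E analogously from Cov_E.

Standard errors come from the delete-one-association jackknife,
SE² = ((g−1)/g) Σᵢ (θ₍ᵢ₎ − θ̄)², re-running the whole pipeline with each
association left out.  Negative moment variances are flagged and make r_G
"undefined" rather than being clamped to zero.  Each fitness component is
also analysed by a three-way fixed-effects ANOVA (M × R × ST) with pooled-t
post-hoc home/away contrasts.

## Worked example

Simulate one study-like experiment and run the full analysis:

```bash
rhizocorr run --preset study --seed 1 --out demo --quiet
```

prints the per-environment correlation table

```
environment  n   r_G  se_rG   r_E  se_rE
  carvacrol 12 0.404  0.372 0.501  0.139
    control 12 0.359  0.485 0.208  0.172
```

and writes ANOVA tables, genotypic-mean tables with major-axis fits, and a
JSON report (jackknife replicates, diagnostics, run log) under `demo/`.
Read it as: on this single simulated dataset the carvacrol-soil genetic
correlation estimate is 0.40 with a jackknife SE of 0.37 over n = 12
associations — one experiment of this size carries large sampling error,
which is exactly what the recovery analysis below quantifies (the
generative values here are r_G = 0.6 on carvacrol soil, 0 on control soil).

The same stages are scripted as a narrative under `analysis/`:

```bash
python analysis/01_simulate.py   # 180-plant table  -> results/simulated_data.csv
python analysis/02_anova.py      # ANOVA tables + home/away contrasts
python analysis/03_gencorr.py    # r_G / r_E with jackknife SEs, major axes
python analysis/04_recovery.py   # 500-experiment estimator calibration
```

`04_recovery.py` reports, for the study's size (g = 12, k = 5):

```
control    true r_G = 0.00  mean r_G-hat = -0.010  SD = 0.449  mean jackknife SE = 0.515 (ratio 1.15)
carvacrol  true r_G = 0.60  mean r_G-hat = +0.554  SD = 0.368  mean jackknife SE = 0.457 (ratio 1.24)
```

i.e. the moment estimator is nearly unbiased at this size, and the
jackknife SE tracks the true across-experiment spread within ~25%.

## Layout

- `src/rhizocorr/` — library: `io` (table model, balance checking),
  `simulate` (calibrated generator), `anova`, `gencorr` (the estimator),
  `recovery`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers writing to `results/`
- `tests/` — pytest suite (unit, property and acceptance-level tests)
- `docs/methods.md` — model, calibration and design choices in detail
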