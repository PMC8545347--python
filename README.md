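# gescan

Genome-wide **gene–environment interaction (GEI) scanning** for biobank-scale
cohorts, with support for multiple interaction terms, interaction covariates,
and heteroskedasticity-robust inference — for statistical geneticists and
genetic epidemiologists running single-variant G×E scans on continuous or
binary traits.

## The model

For individual *i* with outcome *Yᵢ*, covariates *Xᵢ* (intercept included),
and the dosage *Gᵢ* of one variant, gescan fits the generalized linear model

```
g(μᵢ) = Xᵢ βX + Gᵢ βG + Cᵢ βC + Sᵢ βS ,     μᵢ = E(Yᵢ | Xᵢ, Gᵢ)
```

where *Sᵢ* are the **q tested interaction terms** (products of *Gᵢ* with the
chosen exposures), and *Cᵢ* are **c interaction covariates** (products of
*Gᵢ* with confounding covariates — adjusted for, never tested). The link
*g(·)* is identity (gaussian family) or logit (binomial family).

Fitting this model separately at millions of variants repeats the same
covariate adjustment millions of times. gescan instead fits the
covariate-only null model **once**, then residualizes each variant's block
`D = [G | G·C | G·S]` on the covariates at the null-model working weights
(a weighted Frisch–Waugh–Lovell projection) and forms one-step estimates

```
β̂ = (D̃' W D̃)⁻¹ D̃' (y − μ̂)
```

with either the model-based covariance `φ (D̃' W D̃)⁻¹` or the HC0 sandwich
`(D̃'WD̃)⁻¹ D̃' diag(e²) D̃ (D̃'WD̃)⁻¹`. Three chi-square p-values are reported
per variant:

* **interaction** (q df): `βS = 0`,
* **joint** (q+1 df): `βG = βS = 0`,
* **marginal** (1 df): the genetic effect in a model with no interaction
  terms.

For the gaussian family the projection reproduces the full-model OLS fit
*exactly* (coefficients, SEs, and p-values); for the logit family it is a
one-step approximation at the null-model weights whose p-values track full
IRLS refits to high accuracy. Robust (sandwich) standard errors protect the
interaction test against mis-specified exposure–outcome relationships
(e.g. an unmodeled quadratic exposure effect), which otherwise inflate
type-I error.

## Worked example

Simulate a 100-sample, 20-variant dataset in which one standard-normal
exposure explains 10% of the outcome variance and interaction effects
explain 5%, then scan it:

```bash
gescan simulate --n 100 --variants 20 --r2-e 0.1 --r2-gxe 0.05 \
    --seed 7 --out-prefix sim
gescan scan --pheno sim.pheno.tsv --outcome outcome \
    --covariates e1 --exposures e1 \
    --genotypes sim.dosages.tsv --out results.tsv
```

The scan logs

```
INFO analyzing 100 samples (100 genotype samples matched)
INFO scan complete: 20 variants, 20 tested, 0 skipped_maf, 0 skipped_missing, 0 singular, 0 with interaction P < 5e-08
```

and writes one row per variant to `results.tsv`; for the first variant:

```
SNPID  CHR  POS   ...  AF     Beta_G     SE_Beta_G  Beta_G-e1  ...  P_Value_Marginal  P_Value_Interaction  P_Value_Joint  STATUS
rs1    1    1000  ...  0.295  0.0244368  0.164779   0.0306984  ...  8.450502e-01      8.451153e-01         9.685823e-01   ok
```

`Beta_G` is the genetic main effect, `Beta_G-e1` the G×e1 interaction
effect, and the three p-values are the marginal, interaction and joint
tests described above (robust SEs are the default; `robust_SE_*` columns
carry them). At n = 100 nothing is significant — the point of the example
is the file format and the three tests. Interaction covariates are declared
with `--int-covariates` (e.g. testing G×sex while adjusting for G×BMI:
`--exposures sex --int-covariates bmi`).

The same machinery is available as a library (`gescan.fit_null_model`,
`gescan.test_variant`, `gescan.run_scan`) and the simulation framework as
`gescan.SimConfig`, `gescan.estimate_type1_error`, `gescan.estimate_power`.

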