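# Methods

## The projection engine

The scan operates on a single covariate-only null fit per phenotype.

**Null model.** `fit_null_model` fits `g(μ) = Xβ` by closed-form weighted
least squares (gaussian/identity) or by IRLS (binomial/logit; tolerance
1e-8 on the maximum coefficient change, at most 30 iterations, started at
β = 0 with the intercept at logit of the outcome mean). The fit retains the
working weights `w` (1 for gaussian, μ(1−μ) for logit), the raw residuals
`r = y − μ̂`, the dispersion φ (RSS/(n−p) for gaussian, fixed 1 for
binomial) and `(X'WX)⁻¹`. Non-convergence and fitted probabilities pinned
at 0/1 (separation) are surfaced as warnings with the last iterate
retained; a rank-deficient covariate matrix raises an error naming the
collinear columns.

**Per-variant step.** For dosage vector g the design
`D = [g | g·C-block | g·S-block]` is residualized on X at the null
weights, `D̃ = D − X(X'WX)⁻¹X'WD`, and the one-step estimate is
`β̂ = (D̃'WD̃)⁻¹ D̃'r`. For the gaussian family this is exactly the
Frisch–Waugh–Lovell decomposition of the full OLS fit of
`y ~ X + G + G·C + G·S`; the one-step residuals `r − D̃β̂` are exactly the
full-model residuals, and the per-variant dispersion is refreshed from
their sum of squares (over n − p − k degrees of freedom), so model-based
SEs and p-values coincide with the full refit to machine precision. For the
logit family the step is a one-step approximation at the null weights;
concordance with full IRLS refits is verified in the test suite
(Pearson r > 0.99 on −log10 p, max discrepancy < 0.5 at n = 5000 with
moderate effects).

**Covariances.** Model-based: `φ (D̃'WD̃)⁻¹`. Robust: the HC0 sandwich
`(D̃'WD̃)⁻¹ D̃' diag(e²) D̃ (D̃'WD̃)⁻¹`, where `e` are the one-step-updated
residuals `r − w·(D̃β̂)` — for gaussian, exactly the textbook HC0 of the
full model. No small-sample (HC1–HC3) correction is applied; at biobank n
the leverage corrections are negligible, and the estimator's finite-sample
behaviour is characterized below. `robust_covariance` also accepts an
explicit residual vector; its default is the null-fit residuals, which is
the appropriate choice for score-type use.

**Tests.** Wald quadratic forms against upper-tail chi-square: the S-block
(q df, interaction), the (G, S) block (q+1 df, joint), and g residualized
alone (1 df, marginal — a model with no interaction terms, which is free
under projection). The C-block is estimated and reported but never tested.
P-values are computed from the log survival function and floored at the
smallest positive double, so underflow never produces a literal 0; the
results writer prints them in scientific notation with six significant
digits.

## Filters and conventions

* Dosages count the effect allele (ALT in VCF); no minor-allele flipping.
  AF is the effect-allele frequency; the MAF filter uses min(af, 1−af)
  with default threshold 0.005.
* Missing dosages are mean-imputed when the missing rate is at most the
  configured maximum (default 5%); variants above it, or entirely missing,
  are skipped with an explicit status so row counts reconcile. Monomorphic
  or collinear variant designs are emitted with `singular` status rather
  than dropped.
* Multi-allelic VCF records are skipped with a warning (effect-allele
  semantics would be ambiguous); positions are 1-based and passed through.
* The scan path uses no randomness, partitions work into variant blocks,
  and buffers results in input order, so output is byte-identical for any
  worker count.
* No multiple-testing correction is applied; 5×10⁻⁸ is a reporting
  convention (`alpha_report`).

## The generative model

`simulate_phenotype` builds a continuous liability as a sum of empirically
standardized components scaled by the square root of their variance
fractions:

* **genetic main** — equal effects over the causal variants (standardized
  dosage columns summed, composite standardized);
* **exposure main** — the sum of the active exposures (first K),
  standardized; in the mis-specification mode the exposures enter squared
  while the analysis model remains linear. With several active exposures
  the main-effect variance is split equally across them;
* **interaction** — equal effects over causal-variant × active-exposure
  products, composite standardized, so the total interaction variance is
  exact and each variant (and each of the K exposures) carries an equal
  share;
* **noise** — gaussian with the remaining variance.

Binary outcomes threshold the liability at the quantile giving the
configured case:control ratio (default 1:3, i.e. 25% cases). Genotypes are
independent Binomial(2, maf) dosages with maf ~ U(0.05, 0.45) by default;
exposures are standard normal, standardized Bernoulli(0.5), or
standardized log-normal, optionally with a configurable variance fraction
explained by the causal dosages (gene–environment correlation). Each
generation stage draws from its own seeded stream, so stages can be called
separately without stream overlap, and identical seeds reproduce files
byte-for-byte.

What the generator deliberately does **not** emulate: linkage
disequilibrium between variants (irrelevant to per-variant calibration and
power, but required for locus-level claims), relatedness/population
structure, genotype missingness or imputation error, and
exposure-measurement error. Passing calibration and power tests therefore
validates the per-variant statistics, not locus discovery on structured
real data.

## Operating-characteristic estimation

**Type-I error** (`estimate_type1_error`): the tested variants carry no
effects; each replicate draws fresh exposures and a fresh phenotype with
the exposure main effect (optionally quadratic) and tests all variants.
Defaults in the calibration suite: n = 50,000 per replicate, 200
replicates × 100 variants = 20,000 null tests per setting, α ∈ {0.05,
1e-3}, with exact binomial acceptance bands around nominal. The sample
size matters: HC0 robust tests with heavy-tailed interaction regressors
(the log-normal exposure) approach their asymptotic level slowly and are
measurably anticonservative at n of a few thousand; n = 50,000 is in the
asymptotic regime while remaining far below the biobank scale the method
targets. Genome-wide α = 5×10⁻⁸ calibration would need ~10⁹ null tests and
is out of scope.

**Power** (`estimate_power`): replicated phenotypes over a fixed causal
variant set; power is the fraction of interaction tests below α. The
analytic companion is the noncentral chi-square with
ncp = n·R²_test/σ²_resid, where R²_test is the per-variant interaction
variance captured by the tested exposures
(R²GxE,total/n_causal · min(q,K)/K) and σ²_resid the residual variance of
the per-variant analysis model (exposure main effects and the tested
variant's own effects removed; the other causal variants' effects remain).
The empirical robust-SE power runs one to a few points below this
approximation because the sandwich correctly charges the
exposure-dependent residual variance contributed by the remaining
interaction effects.

The headline power computation (acceptance script) uses the full
n = 352,768 with 100 variants × 10 replicate phenotypes = 1000 tests at
α = 5×10⁻⁸. The power-*shape* suite (monotonicity in total interaction
variance; decrease with test df at K = 1; decrease when testing subsets of
10 active exposures; near-invariance to adding a 0.1% per-variant main
effect) runs at n = 100,000 with 5 replicates × 100 variants per
configuration and evaluates at α = 1e-4, where the contrasts are
resolvable at these replicate counts; the shapes themselves are
α-independent.

## Design choices and limitations

* The null model contains all covariates (exposures included) as main
  effects only; G, C and S enter per-variant via projection. This is the
  only structure under which one null fit amortizes across millions of
  variants.
* Binomial per-variant inference is Wald-type in the projected space at
  null weights (no per-variant IRLS). For case-control ratios much more
  extreme than ~1:9 asymptotic logistic tests of this type are known to
  deteriorate; a saddlepoint-calibrated method should be used there
  instead.
* Relatedness is not modeled; the engine assumes unrelated samples.
* BGEN/PGEN binary genotype formats, INFO-score computation, LD clumping
  and annotation are out of scope; `info_score` on a variant record is
  pass-through only.
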