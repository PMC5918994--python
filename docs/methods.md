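# Methods

## Problem and model

A single-sample SNV call list of size N can be viewed as N binary
trials: each call is either a true variant (TP) or a false one (FP).
The observed positive predictive value is PPV = TP/N = TP/(TP+FP). On
gold-standard samples (e.g. NA12878, where the true variants are known)
TP and FP can be counted explicitly; the goal is to predict, for a call
list *without* a truth set, the observed PPV from call-set summary
statistics alone: the transition/transversion ratio (Ti/Tv), the
heterozygous/homozygous-alternate ratio (Het/Hom), the median depth of
called variants (MedDp), the fraction of calls with depth below 5
(DpLt5), and a WES/WGS indicator.

A plain Binomial regression of Y = TP on these covariates is severely
overdispersed across call sets, so the TP count is modelled
Beta-binomially in the mean/dispersion parameterization:

    E[Y]   = N μ
    Var[Y] = N μ(1−μ) (1 + Nσ) / (1 + σ)

with the Beta-shape bridge α = μ/σ, β = (1−μ)/σ; σ = 0 is the Binomial
limit, σ → ∞ approaches maximal overdispersion Var[Y] → N²μ(1−μ).
Covariates enter both parameters:

    μ = logistic(x′β),   σ = exp(z′γ)   (log link; default)
    σ = (z′γ)^(1/λ)                     (Box-Cox family, z′γ > 0)

A model is labelled (p, q) by the lengths of β and γ; z is always a
subset of x. Quantitative covariates are centered to their training
means before any squared or interaction term is formed; the binary WES
indicator is never centered. Centering constants (and factor level
orders) are stored in the fitted model so new call sets are always
evaluated on the training scale.

## Named model specifications

- `m11_6` — the selected model. Mean part (11 terms): intercept, WES,
  Ti/Tv, MedDp, DpLt5, Ti/Tv², MedDp², WES·Ti/Tv, WES·MedDp, WES·DpLt5,
  Ti/Tv·MedDp. Dispersion part (6): intercept, WES, Ti/Tv, DpLt5,
  Ti/Tv², WES·Ti/Tv.
- `m11_1` — same mean part, intercept-only dispersion.
- `global_mean_18` — the full second-order starting pool: intercept,
  5 main effects, 4 squares, 4 WES interactions, MedDp·Het/Hom,
  Ti/Tv·MedDp, Ti/Tv·DpLt5 (17 enumerable terms) plus a configurable
  18th slot defaulting to Ti/Tv·Het/Hom.
- `m15_1` — the 18-term pool minus the purely exploratory Het/Hom²,
  DpLt5² and Ti/Tv·Het/Hom terms, retaining the Het/Hom main effect and
  its WES/MedDp interactions. The exact 15-term list reached by
  elimination on the original training data is not recoverable from its
  description, so this list is this package's own choice; nothing
  downstream depends on it.

Preparation-kit and caller factors (for (19, 1)-style models) are
supported generically through treatment coding (first level is the
reference: WGS, Samtools) via user-supplied term lists.

## Estimation

The exact joint Beta-binomial likelihood is maximized over (β, γ) —
not a backfitting scheme — using L-BFGS-B with analytic gradients,
followed by a damped-Newton polish on the gradient (accepted on
gradient-norm decrease). Numerical choices that matter:

- **Stable log-likelihood.** For tiny σ the shapes α, β reach 1e9+ and
  the naive `lgamma` differences lose about half the mantissa; the
  engine computes ln Γ(base+k) − ln Γ(base) by a series in k/base once
  base > 1000·k (error < 1e−8), which keeps line searches noise-free.
- **Dispersion floor.** The dispersion linear predictor is clipped to
  [−20, 10]; σ below e⁻²⁰ ≈ 2e−9 is numerically Binomial for any
  realistic call-list size, and the likelihood is treated as exactly
  flat beyond the clip (zero gradient), keeping the objective and its
  gradient consistent.
- **Column standardization.** Design columns are rescaled internally to
  unit max-absolute-value (MedDp² columns are ~10⁴ times larger than
  DpLt5 columns otherwise); estimates, standard errors and the
  covariance are transformed back afterwards.
- **Starting values.** β from an N-weighted least-squares fit to the
  empirical logits; the γ intercept from a method-of-moments
  overdispersion estimate; remaining γ at zero. Warm starts (e.g. the
  full-data optimum during leave-one-out) are accepted directly.
- **Convergence.** `ftol` 1e−8 relative, max 500 iterations; a fit is
  flagged non-convergent (never silently accepted) if both the
  optimizer and the polish fail their criteria.
- **Inference.** Standard errors come from the inverse observed
  information (central finite differences of the analytic gradient);
  p-values are two-sided Wald z-tests against the standard Normal.
  AIC = −2·loglik + 2(p+q); Akaike weights are
  exp(−Δᵢ/2)/Σ exp(−Δⱼ/2).
- **Box-Cox links.** Infeasible points (z′γ ≤ 0) receive a smooth
  quadratic penalty rather than a hard failure, so the optimizer can
  re-enter the feasible half-space.

## Prediction intervals

For a new call set with statistics x (and size N), the fitted μ̂ and σ̂
give the Normal-approximation 95% interval for the *observed*
proportion Y/N:

    μ̂ ± z₀.₉₇₅ · sqrt( μ̂(1−μ̂)(1+Nσ̂) / ((1+σ̂) N) )

with the exact quantile z₀.₉₇₅ ≈ 1.959964, truncated to [0, 1]
afterwards; interval lengths (reported in percent) are measured after
truncation. Coefficient-estimation uncertainty is deliberately ignored
— the interval targets the future observation given the fitted
surface, which is adequate when the training set is large relative to
p + q. Calibration is assessed by leave-one-out coverage: each
training row's interval comes from a refit without that row
(warm-started at the full-data optimum; non-convergent refits are
excluded with a logged count), and coverage is the fraction of observed
proportions inside their own interval. Five-number summaries of PI
lengths use R type-7 (linear interpolation) quantiles; an optional
restriction keeps only intervals whose point estimate exceeds a PPV
threshold (e.g. 95%). Quantitative covariates outside the training
range trigger an extrapolation warning, not an error.

## Model selection

Backward elimination is p-value driven with an AIC stopping rule:
removable candidates (intercept excluded; a main effect is frozen while
any of its squares/interactions remain; mean-part terms still in the
dispersion part are frozen) are tried in decreasing Wald-p order and
the first removal that lowers AIC is accepted; the procedure stops when
no removal lowers AIC. Ties are broken by dropping the higher-order
term first, then alphabetically. The full trace (term, p-value, AIC
before/after) is returned. Note a consequence of AIC gating: a single
pure-noise term is removed with asymptotic probability
P(χ²₁ < 2) ≈ 0.84, not 0.95 — AIC is a laxer gate than p < 0.05.
Elimination treats one part at a time (mean first with intercept-only
dispersion, then the dispersion part with the mean fixed), mirroring
the two-stage workflow the selected models came from.

The dispersion-link scan fits the spec under σ = (z′γ)^(1/λ) for
1/λ ∈ {2, …, 10} by default, plus the log link as the λ = 0 reference,
and reports AIC per λ; on data generated under the log link the λ = 0
row attains the minimum.

## Diagnostics

- **Weighted residuals** are normalized randomized quantile residuals:
  u ~ Uniform(F(y−1), F(y)) under the fitted Beta-binomial CDF, mapped
  through Φ⁻¹; approximately N(0, 1) under a well-specified model. The
  randomization seed is fixed (default 20180425) for reproducibility.
  The CDF is an own vectorized pmf summation (exact, fast for the
  N ~ 10⁴–10⁵ regime).
- **Hat values** use the Binomial working model under the logit link:
  diag of W^{1/2}X(X′WX)⁻¹X′W^{1/2} with wᵢ = Nᵢμ̂ᵢ(1−μ̂ᵢ); they sum
  to p. Exact Beta-binomial leverage is not defined here; these are
  screening quantities.
- **Cook's distances** use the one-step GLM approximation
  Dᵢ = r²ᵢhᵢ/(p(1−hᵢ)²) with raw Binomial Pearson residuals; under
  Beta-binomial overdispersion the absolute values run large and only
  the ranking should be interpreted.
- Default flags: |r| > 3, h > 2p/n, D > 4/n; `refit_without` reports
  each coefficient's shift (in SE units) after deleting flagged rows —
  the workflow that isolates, e.g., a high-Het/Hom covariate-space
  outlier.

## Synthetic data

`simulate_training_table` draws covariates independently and uniformly:
Ti/Tv in [1, 3.5], Het/Hom in [1, 7], MedDp in [5, 150], DpLt5 in
[0, 0.5], WES ~ Bernoulli(0.5); call-list sizes N are log-uniform in
[10⁴, 10⁵], bracketing the tens-of-thousands scale of filtered human
WES/WGS call lists. The default coefficient vectors are the fitted
(11, 6) estimates from NA12878 WES/WGS gold-standard call sets, so the
default tables reproduce the covariate-to-PPV surface and dispersion
structure such a study observes; Y is drawn by the exact
Beta(α, β)-then-Binomial composition. An optional rank-coupling knob
induces the negative Ti/Tv–Het/Hom association seen in real call sets.
The generator emulates the *statistical* structure only: covariates are
uniform rather than clustered by pipeline, rows are independent
(real call lists derived from the same sample/caller are not), and no
read-level error profile exists. Passing calibration tests therefore
demonstrates correctness of the estimation machinery under the model's
own assumptions, not robustness to real-data misspecification.

`simulate_vcf_pair` fabricates a truth set and a call set equal to
truth plus a chosen number of false positives at disjoint positions
(true calls target Ti/Tv ≈ 2.5, false calls ≈ 0.5, mimicking how false
positives depress Ti/Tv), so validation must return exactly the
constructed TP/FP counts. Het fraction defaults to 2/3 (Het/Hom ≈ 2);
depths are Poisson with mean 30.

## Validation semantics

Calls and truth are restricted to confident regions first; a call is a
TP iff a truth record matches on (contig, pos, ref, alt) and — by
default — genotype class (a genotype mismatch at a shared site counts
one FP and one FN); `genotype_aware=False` relaxes to site/allele
identity. Duplicate records count once, so TP + FP equals the filtered
call count N. Specificity is reported as not applicable: true negatives
are ill-defined without a site universe. Multi-allelic sites are
decomposed into one record per alt allele; VCF positions are 1-based,
BED intervals 0-based half-open, and contig names are compared after
stripping a leading "chr".

## Problem sizes

Simulation-based checks use 500-row tables (the scale of the original
training set) and 50 replicates for recovery/selection rates; the
leave-one-out run refits ~500 models warm-started at the full-data
optimum (a few hundredths of a second per refit).

## Known limitations

- Single-sample VCFs only; the first sample is read.
- Indels, structural variants and half-missing genotypes are excluded
  by design; mitochondria, chrY and unplaced contigs are outside the
  modelled call universe (abnormal Ti/Tv regimes need a separate
  model).
- Coefficient-uncertainty-free prediction intervals undercover slightly
  when the training table is small relative to p + q.
- Hat values and Cook's distances are Binomial-approximation screening
  tools, not exact Beta-binomial influence measures.
- Het/Hom is ancestry-dependent; a model trained on one individual
  cannot carry a transferable Het/Hom effect across ancestries.
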