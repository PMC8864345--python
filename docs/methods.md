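# Methods

## Model

Each study *i* in a meta-analysis reports a standardized mean difference
(Cohen's *d*) estimate *y*<sub>i</sub> with known sampling variance
*v*<sub>i</sub>. The working model is the standard normal–normal
hierarchy:

    theta_i ~ N(mu, tau2)        (population effect of study i)
    y_i | theta_i ~ N(theta_i, v_i)

so marginally *y*<sub>i</sub> ~ N(μ, v<sub>i</sub> + τ²). The pooled mean
uses weights w<sub>i</sub>\* = 1/(v<sub>i</sub> + τ̂²); its standard error
is (Σw<sub>i</sub>\*)<sup>−1/2</sup>. All estimates are assumed
sign-harmonized so the hypothesized direction is positive; the CSV loader
has a `direction_flip` column for inputs that are not.

The multi-laboratory replication (MLR) enters as a single high-precision
summary estimate per phenomenon. It is treated as a *fixed, known*
threshold in the calibrated-proportion analysis; its own sampling error
is not propagated (it is an order of magnitude smaller than the
between-study spread the metric summarizes).

## Heterogeneity estimation

Three τ² estimators are provided; all truncate at 0:

* **DL** (DerSimonian–Laird): closed-form moment estimator
  max(0, (Q − (k−1))/C), C = Σw − Σw²/Σw, w = 1/v.
* **PM** (Paule–Mandel, the default): solves the generalized-Q estimating
  equation Q<sub>gen</sub>(τ²) = k−1 by Brent root-finding bracketed on
  [0, 100] (in d² units, far above any plausible value; the bracket is
  widened ×10 up to six times in pathological cases) with tolerance
  1e−8; returns 0 when Q<sub>gen</sub>(0) ≤ k−1. PM is the default
  because it is the convention of the selection-model sensitivity
  literature this package implements.
* **REML**: bounded scalar minimization of the restricted negative
  log-likelihood on [0, 100] (xatol 1e−10), with an explicit snap to 0
  when the boundary value is at least as good — bounded Brent never
  evaluates the boundary exactly.

With k = 1, τ² is unidentified: the estimate is 0 with a warning, and the
fit is the passthrough (μ̂ = y₁, se = √v₁, flagged `low_k`). Single-study
inputs are legal throughout because the worst-case analysis can leave a
single non-affirmative study.

95% intervals for μ̂ are Wald-z by default (plain CIs, no small-sample
correction) or Hartung–Knapp–Sidik–Jonkman (variance rescaled by the
weighted residual mean square, t(k−1) critical value) via
`interval_method="hksj"`. The DL/PM/REML fits and the HKSJ interval were
cross-checked against R `metafor::rma` on a frozen five-study fixture
(agreement ~1e−6, limited by root-finding tolerances).

## Calibrated effect distributions

Given a fit, each study's population effect is estimated by shrinkage
toward the pooled mean,

    gamma_i = mu_hat + tau2_hat/(tau2_hat + v_i) * (y_i - mu_hat),

and the empirical distribution of the γ̂<sub>i</sub> estimates the
distribution of population effects across studies. The raw estimates
cannot be used directly for this because their spread mixes real
heterogeneity with sampling noise; shrinkage removes the latter. Limits:
τ̂² = 0 collapses every γ̂<sub>i</sub> to μ̂; v<sub>i</sub> → 0 leaves
y<sub>i</sub> unshrunk.

The headline metric is P̂(q) = #{γ̂<sub>i</sub> ≤ q}/k with q the MLR
estimate. The comparison is inclusive (≤), reading "as small as, or
smaller than" literally. Its 95% CI comes from a bias-corrected and
accelerated (BCa) bootstrap that resamples whole studies with replacement
— the only resampling level study-level data supports — and refits the
meta-analysis (same τ² estimator), recalibrates and recounts in every
replicate (default n_boot = 1000, minimum 200; the seed is mandatory in
the pipeline). The BCa construction is scipy's (`scipy.stats.bootstrap`,
paired resampling; bias correction z₀ from the bootstrap distribution,
acceleration from the leave-one-out jackknife). When the bootstrap
distribution is degenerate (e.g. every replicate yields the same
proportion, making z₀ infinite) the interval is reported as *not
estimable* rather than fabricated, matching the convention of omitting
such CIs; estimable bounds are clipped to [0, 1]. A percentile bootstrap
is kept selectable purely as a coverage cross-check in the tests.

## Publication-bias sensitivity analysis

The selection model: a study is **affirmative** if its two-sided p-value
is below α (default 0.05) *and* its estimate is positive — equivalently
z = y/√v > z<sub>1−α/2</sub> — and **non-affirmative** otherwise
(non-significant or negative). Affirmative studies are η ≥ 1 times more
likely to be published, with no further selection on the estimate's size.
A normal (z) reference is used for classification; study-level degrees of
freedom are not available from (y, v) pairs.

Under that model, published non-affirmative studies are a random sample
of all non-affirmative studies, so a known η can be undone by
up-weighting each published non-affirmative study η-fold:

    corrected_mu = sum(w_i~ y_i) / sum(w_i~),
    w_i~ = eta/(v_i + tau2_hat)  (non-affirmative),  1/(v_i + tau2_hat)  (affirmative).

τ̂² is estimated **once on the full published dataset** and held fixed
inside the reweighting. This keeps η's effect isolated to the mean and
makes the correction exactly equivalent to replicating each
non-affirmative study η times in a plain weighted mean (the
"replication-equivalence" oracle used in the tests). η = 1 reproduces the
naive fit to 1e−10.

The **worst case** (η → ∞) is an ordinary random-effects meta-analysis of
the non-affirmative subset alone, with τ² re-estimated on that subset (it
is simply a meta-analysis of those studies). It is *not estimable* when
every study is affirmative — reported as a flag, never an exception.
Because the subset τ² differs from the full-data τ², the numeric η → ∞
limit of `corrected_estimate` matches the worst case only under matched
τ² handling; the tests compare them that way. Note the worst case is a
*bound*, not an unbiased correction: even with no publication bias at
all, discarding the significant-positive studies biases the subset mean
downward in any well-powered literature. It approaches the naive estimate
only when affirmative studies are rare.

## Cross-phenomenon comparison

Pearson's r between naive pooled means and MLR estimates, with the
Fisher-z interval tanh(atanh r ± 1.96/√(n−3)) and the two-sided p from
t = r√((n−2)/(1−r²)) on n−2 df — the construction that reproduces
R `cor.test` to 1e−6 (verified at the reference configuration r = 0.72,
n = 15, which yields [0.329, 0.900], p = 0.0025). The OLS line regresses
MLR on meta-analytic estimates.

The worst-case summary filters to phenomena where the naive mean strictly
exceeds the MLR estimate *and* the worst case is estimable, then reports:
mean naive and worst-case estimates, the **mean of per-phenomenon
worst/naive ratios** and, separately, the **ratio of the means** (the two
differ; both are reported because either reading is defensible), mean
|naive − worst|, and the fractions of phenomena with worst-case > MLR and
worst-case > 0 (strict inequalities on point estimates). The
per-phenomenon ratio is numerically unstable when a naive mean is near
zero; the filter (naive > MLR) usually, but not always, protects against
this — the ratio of means is the stabler companion. The median of P̂ is
reported both over all phenomena with a defined metric and over the
filtered set, since either denominator is a reasonable convention.

`run_full_comparison` sorts phenomena by identifier and derives one
bootstrap seed per phenomenon from the config seed, making reports
byte-identical across runs and invariant to input order.

## Synthetic data

The generator draws candidate studies exactly under the working model —
θ ~ N(μ_true, τ²_true), total sample size n uniform on a range,
v = 4/n (the standard two-arm SMD variance scaling), y ~ N(θ, v) —
classifies each, publishes affirmative studies with probability 1 and
non-affirmative ones independently with probability 1/η (Bernoulli
selection on affirmative status only), and stops at k_published studies.
The MLR is one draw from N(mlr_mu, 4/mlr_n). A generation budget of
200 000 candidate draws guards against unattainable configurations and
raises with diagnostics.

Suite defaults (chosen once as a plausible psychology-style literature):
15 phenomena; per-phenomenon μ ~ N(0.3, 0.15²); τ² ~ U(0.01, 0.21),
centred on 0.11, the middle of the heterogeneity range reported across
the motivating sample of meta-analyses (0–0.54); η = 5 (the worked
"five times more likely" selection scenario); k_published ~ U{10..40};
per-study n ~ U{40..200}; mlr_n = 4000; and mlr_mu = μ − 0.10, so that
part of the meta-analysis/MLR gap is substantive rather than
selection-induced — emulating the conclusion that publication bias alone
does not explain the observed discrepancy. Setting η = 1 and the offset
to 0 gives a no-discrepancy world.

What the generator does **not** emulate: site-by-stimulus context
sensitivity, p-hacking/continuous selection on p-values, correlated
effects within labs, non-normal population-effect distributions, or
variance estimates that depend on the estimate itself. Passing recovery
tests therefore show the estimators are correct *under the assumed
selection model*, not that real literatures satisfy it.

## Problem sizes and tolerances

Oracle-equivalence tests use 100+ random datasets with k ∈ 2..10
(PM vs. bisection to 1e−6; REML vs. a τ² grid of step 1e−4 to 1e−3;
means/Q/r to 1e−8 or better). Recovery experiments use 300 replicates at
k = 60 for the η = 5 correction, 500 at k = 40 for unbiasedness without
selection, 200 at k = 50 for quantile recovery of P̂, and 120 simulated
meta-analyses (k = 30, n_boot = 200) for the BCa/percentile coverage
check with an ≥ 85% acceptance floor absorbing Monte-Carlo error at
nominal 95%. These sizes keep the full suite under a minute while leaving
Monte-Carlo error well inside the asserted bands.

## Limitations

* The corrected estimate returns a point estimate only; no
  cluster-robust or inflated-variance inference is attached to it.
* The MLR's sampling error is ignored in the proportion metric.
* η is never estimated from data; three-parameter selection likelihoods,
  trim-and-fill and PET-PEESE style corrections are deliberately out of
  scope.
* Meta-regression, multilevel models and effect-size conversion from raw
  statistics are out of scope; inputs must already be (d, v) pairs.
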