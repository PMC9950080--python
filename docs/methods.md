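# Methods

## Model

Each trial of item *i* by person *p* is Bernoulli with success probability
given by the equal-variance Gaussian m-AFC psychometric function

    Pc(d; m) = ∫ φ(x − d) Φ(x)^(m−1) dx,     d = θp − bi,

the probability that a draw from N(d, 1) exceeds the maximum of m−1
independent N(0, 1) draws. Key properties relied on throughout: Pc is
strictly increasing in d, Pc(0; m) = 1/m (chance), Pc → 0/1 in the tails,
and for m = 2 it reduces to Φ(d/√2). Trials are conditionally independent
given (θ, b); per-cell successes are therefore binomial, and the 0–3 summed
score over the standard three trials is a sufficient statistic.

Persons and items share one *relative d′* axis. The likelihood depends only
on differences θp − bi, so the scale origin is fixed by anchoring the mean
person measure at zero: d′ = 0 is chance performance for the average person
in the sample. Items with b > 0 are performed below chance by that average
person — a natural outcome at the lowest visibility levels, handled by the
model without special-casing.

The Rasch baseline replaces Pc with the logistic function of θp − bi on
trial-level dichotomous data, estimated with the identical machinery and
anchoring. Because the logistic link has no chance floor, fitting it to
mixed-m forced-choice data absorbs the guessing floor into the item
parameter: items of equal latent difficulty but different m separate on the
logit scale (higher m → lower chance success rate → larger Rasch
difficulty; empirically ≈ 0.70 logits between m = 2 and m = 3 and ≈ 1.10
between m = 2 and m = 4 at equal d′). `compare_sdt_rasch` quantifies this by
regressing Rasch difficulty on SDT measure within each m stratum and
reporting intercepts with SEs.

## Estimation

Joint maximum likelihood (JMLE), alternating damped Newton updates between
the person and item blocks. Given one block, the other decomposes into
independent one-dimensional problems, so each cycle is two vectorized
per-coordinate Newton steps (clipped at 1.0; a fallback half-step of
sign(gradient)·0.5 is used where curvature is not negative). After every
cycle both blocks are shifted by the person mean, which enforces the anchor
without changing the likelihood. Convergence is declared when the
log-likelihood changes by less than `tol` (default 1e−8); typical fits
converge in 5–10 cycles.

Numerical choices:

- **Quadrature.** Gauss–Hermite of order 61 after the change of variables
  x = √2·t + d, which makes the integrand analytic in t; the order-61 rule
  reproduces 1/m at d = 0 and the m = 2 closed form to machine precision
  (validated in the tests at 1e−9/1e−8). The first and second derivatives
  Pc′ and Pc″ use the same nodes with weights √2·t and 2t²−1, so one Φ
  evaluation per cell serves the probability and both derivatives.
- **Probability clipping.** Pc is clipped to [ε, 1−ε] with ε = 1e−6 to keep
  the log-likelihood finite at extreme offsets.
- **Boundaries.** Parameters are capped at ±5 relative d′ (`param_bound`).
  Perfect or zero scorers — common with only three trials per cell — drift
  to the cap, are flagged `at_bound`, and are *not* dropped, since removing
  them would bias the mean-zero anchor.
- **Initialization.** θ starts at the person's overall success rate mapped
  through the m = 2 closed form (√2·Φ⁻¹(rate), rate clipped to [0.01,
  0.99]); item starts are the analogous map with the sign flipped. Fits from
  random starts agree with the default to < 1e−4 per non-boundary parameter
  (tested), so the initialization is a speed choice, not a result.
- **Ties/ordering.** Persons and items are processed in sorted-id order
  everywhere, making all outputs deterministic.

**Standard errors.** Default is the split-block observed information: each
parameter's SE is the inverse square root of its own second derivative with
the other block held at the MLE. This matches common JMLE practice and is
what the CI-coverage property is stated for. The full joint information
(pseudo-inverse, because anchoring leaves a null direction along a common
shift of both blocks) is available via `se_method="joint"`; it is never
smaller than the split-block SE and close to it when the design is well
filled. SEs are reported as NaN where the information is singular, and
flagged unreliable at the bound. 95% CIs are estimate ± 1.96·SE.

**JMLE caveat.** Joint estimation is known to be inconsistent as either
dimension is fixed while the other grows; with 111+ trials behind every item
and 171 behind every person the bias is small here (item CI coverage across
200 design-matched replicates is ≈ 0.95 in the tests), but the estimator is
not bias-corrected, and conditional or marginal ML are out of scope.

## Brown–Forsythe test

The category comparison uses the Brown–Forsythe (1974) equality-of-means
statistic

    F* = Σ nj (ȳj − ȳ)² / Σ (1 − nj/N) s²j,

with numerator df k−1 and Satterthwaite-approximated denominator df, robust
to unequal group variances (the three categories have very different sizes:
39/9/9 items). The median-centred Levene variant — whose integer df pattern
(k−1, N−k) matches how such tests are often reported — is available with
`variant="median"`. When every group is constant the statistic is undefined
and reported as NaN with p = 1 if the means also coincide. No
multiple-testing correction is applied: the pipeline reports single
pre-specified tests.

The acuity analysis is ordinary least squares of logMAR acuity on person
measure; the slope's two-sided t-test p-value, r², and the mean absolute
residual (logMAR) are reported. Persons without acuity are excluded from the
regression only. A constant acuity vector yields r² = 0 by convention; a
constant predictor sets `slope_undefined`.

## Synthetic data generator

The generator mirrors the calibration study's design, which is the default
configuration:

| parameter | default | why |
|---|---|---|
| n_persons | 37 | study cohort size |
| ability distribution | uniform on [−0.74, 2.2] d′, re-centred to mean 0 | the printed person-measure range is the only distributional fact available |
| difficulty distribution | uniform on [−1.09, 0.39] d′ | printed item-measure range |
| trials per person-item | 3 | administration protocol |
| acuity link | logMAR = 3.3 − 0.25·θ + N(0, 0.40), clipped to [2.0, 3.5] | reproduces the reported mean acuity ≈ 3.2 logMAR, the BRVT floor/ceiling, and r² ≈ 0.2 with ability; noise_sd was calibrated once at large n and frozen |

One master seed spawns four independent substreams (abilities,
difficulties, trial outcomes, acuities), so changing the acuity link leaves
the response draws untouched, and identical configurations are
byte-reproducible. Trial schedules are keyed by (seed, SHA-256 of
person_id), so adding a participant never reshuffles another's order.

What the generator does **not** emulate: learning or fatigue across trials,
trial-order effects, response times, heterogeneous per-person lapse rates,
and any misspecification of the psychometric function itself. Passing
recovery and coverage tests therefore demonstrates the estimator is correct
*under the model*, not that the model is correct for real ULV data.

## Scale choices in the checks

Simulation-based properties use problem sizes chosen to make the relevant
signal unambiguous while keeping the suite quick: recovery at the study
cohort with 30 trials per item, stratification at 500 persons × 30 trials,
CI coverage over 200 design-matched (3-trial) replicates, and the
Brown–Forsythe null at 10,000 vectorized replicates. The brute-force
optimizer oracle enumerates a step-0.05 grid over [−3, 3]³ for a 2×2×10-
trial instance (argmax agreement within one grid step) with a step-0.002
local refinement for the log-likelihood comparison, since a 0.05 grid alone
cannot resolve the optimum to 1e−3 at these curvatures.

The Rasch "SDT does not stratify" half of the comparison is checked on the
absolute scale (per-m intercepts of fitted-vs-true SDT difficulty within
0.05 d′ of each other) rather than in SE units: with 500 persons the
intercept SEs are ~0.003, so SE-relative separation would flag scientifically
negligible offsets, while the Rasch separations at issue are two orders of
magnitude larger (0.7–1.1 logits).

## Known limitations

- The canonical item bank names the activities documented in the main
  instrument description and fills the remaining spatial-localization slots
  with clearly labelled placeholders (correct counts, category split, and m
  values; visibility ladders per axis). Users with the full instrument
  supplement can substitute exact definitions via the JSON document schema
  (`src/ulvfit/data/item_bank_schema.json`).
- Alternatives-with-replacement scheduling and demo trials are modelled
  (demos as unscored annotations), but the analysis itself only consumes
  scored trials.
- No differential item functioning, multidimensional traits, partial-credit
  models, or test equating.
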