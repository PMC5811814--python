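# Methods

## Model

A simulated observer's response to a salary time series is

    BR = SW × EA × (1 + k_p · x_p),      SW = exp(−(S − T)),

a Gaussian random variable whose mean SW·EA and standard deviation
SW·EA·k_p are set by three ingredients:

- **Idealized stimulus item S** ∈ [0, 1]: what kind of experience the
  observer had. Static experience (the whole series at once) is
  summarized by the normalized sequence mean, S = 0.35; dynamic
  experience (value by value, with or without history visible) by the
  normalized last element.
- **Idealized task item T** ∈ [0, 1]: what is asked. Judging the average
  maps to T = 0.35; forecasting the next value to the normalized last
  element.
- **Experience-dependent anchor EA** (pounds): the sequence mean 3,500
  for static experience, the last presented value for dynamic experience.

The similarity weight uses the *signed* distance deliberately: on a
rising trend the last element lies above the mean, so a static-experience
forecast (S = 0.35 < T) gets SW > 1 — an upward but insufficient
adjustment away from the mean anchor — while a dynamic-experience
judgment gets SW < 1, dragging the average estimate toward the recent
values. Exponentials of signed distances also give the reciprocity
SW(S,T)·SW(T,S) = 1, which makes the damping and anchoring deviations
mirror each other up to the convexity of exp.

Perceptual variability enters multiplicatively: each simulated response
draws one standard-normal x_p (one observer, one response). With k_p = 0
the model is deterministic.

### Assumptions worth stating

- Normalization is division by a fixed constant of 10,000 pounds — the
  unique linear map sending the sequence mean 3,500 to 0.35. Per-series
  (min–max) renormalization would be inconsistent with that
  correspondence and is not offered.
- S and T for static/judgment are fixed at 0.35 for every series,
  including inconsistent ones whose realized mean deviates slightly from
  3,500.
- The model cannot distinguish historic-dynamic from momentary-dynamic
  presentation: S, T and EA depend only on the last element in both.
  This is a property of the model, not of the implementation; empirical
  differences between those two modes are outside its reach.
- Responses are continuous; no rounding to whole pounds.

## Stimuli

Series are generated from linear equations with additive Gaussian noise:
intercept/slope pairs (3000, +21.28), (4000, −21.28), (3500, 0) over
months t = 1..48, noise mean 0 and **variance** 10 (SD ≈ 3.16 pounds).
"Variance 10" is taken literally; it is exposed as `noise_variance` for
users who want visually rougher series. Inconsistent variants append a
49th point equal to 3,500 exactly, with no noise: the appended value is a
single stated number, not a draw. The month index is 1-based; a
`t_origin` field on `TrendSpec` supports shifted indexing, because only
with the origin near 0 do the trended deterministic means coincide with
the stationary mean. The judgment reference is nevertheless fixed at
3,500 for all series — the trended zero-noise means are 3,521.36 and
3,478.64, and treating 3,500 as "the true mean for all series" is the
reading adopted throughout; per-cell summaries expose realized means for
anyone who wants the alternative.

## The simulated experiment

The design crosses 3 presentation modes × 3 trend directions × 2
consistency levels, for both tasks (36 cells), with n = 90 simulated
responses per cell by default. Each replicate regenerates the series
noise, so deterministic comparator models also vary within a cell;
`fixed_series=True` freezes one series per cell instead, leaving
perceptual noise as the only source. Dependent variables: forecasting
error = response − regression-predicted next value (the generating
equation one month past the end for consistent series; an OLS refit
through all 49 points, evaluated at month 50, for inconsistent ones), and
estimation error = response − 3,500. Under-prediction of a rising trend
is a negative forecasting error.

Seeding is hierarchical: the master seed spawns one `SeedSequence` child
per cell (recorded in the output), so any cell is reproducible in
isolation; a fixed master seed makes the full response table
bit-identical across runs.

## Comparator models

- **regression_next**: the regression-predicted next trend value,
  weighted by the same multiplicative noise process, PV = Y(t)·(1 + k_p·ξ).
- **arima_100**: AR(1) with constant, fit by conditional least squares
  (the OLS regression of y_2..y_T on its lag — chosen for determinism and
  closed-form testability; exact ML is available via `arima_method="mle"`),
  forecasting c + φ·y_T.
- **exp_smoothing**: simple exponential smoothing, level initialized at
  the first observation, α minimizing the in-sample one-step SSE over
  [0.01, 0.99] (bounded scalar minimization checked against the interval
  endpoints, since trended series push α to the upper bound); the
  forecast is the final level. Damped-trend and seasonal flavors are out
  of scope.

ARIMA and exponential smoothing are pure functions of the series by
default; an opt-in flag applies the multiplicative noise wrapper to them
as well.

## Statistical harness

Unrelated t tests are Student's pooled-variance tests (Levene's test is
what licenses the equal-variance assumption), two-sided, with effect size
r = √(t²/(t²+df)) — the form that reproduces printed (t, df, r) pairings
on this scale. Factorial ANOVA (statsmodels OLS, balanced designs only)
reports ε² = (SS_effect − df_effect·MS_error)/SS_total per effect,
clipped at 0; a constant response yields F = 0, p = 1, ε² = 0 by
convention, and a trailing row carries the residual SS so the
decomposition is checkable. Split-half cross-validation randomly halves a
90-response cell and its 90 model predictions into 45 + 45 and runs the
2×2 series-by-subsample ANOVA; a good, stable fit leaves both the series
main effect and the interaction non-significant.

## Numerical and design choices

- kp defaults to 0.04, imported from prior perceptual-scaling work; it is
  not fit to data here. Its recovery from simulated output uses the
  per-cell SD/|mean| response ratio averaged over cells (the series-noise
  contribution to that ratio is quadratically small at variance 10).
- AR(1) fits on series that are constant to machine precision return the
  constant rather than a degenerate regression.
- The bounded SSE search for α uses xatol 1e-6 and an explicit endpoint
  comparison.
- Problem sizes in the test suite follow the study settings (n = 90 per
  cell, 1,620 pooled forecasts per model) where the claim concerns those
  settings; Monte-Carlo contracts use 10⁴ draws and calibration checks
  1,000 repetitions, sizes at which binomial/sampling error is well
  inside the asserted tolerances.

## What the simulation does and does not show

The generator emulates the stimulus statistics of a behavioral
experiment, not its participants: passing tests show the model and
harness are implemented correctly and that the model's qualitative
predictions (trend damping, recency anchoring, the fourfold accuracy
dissociation, the ARIMA-vs-smoothing null) follow from its equations
under the stated noise. They say nothing about fit to human data, which
is not shipped.

One comparison deserves a caveat: the design is mirror-symmetric about
3,500 (the rising and falling series are reflections of each other), and
any affine-equivariant forecaster — AR(1) with constant, exponential
smoothing, OLS — therefore has a pooled forecast expectation of exactly
3,500; the anchoring model's pooled expectation differs only through the
convexity of exp (≈ +0.5 pounds). Pooled anchoring-vs-ARIMA t tests are
therefore null in expectation under these study conditions, and the
simulator reports them as such; a large pooled difference requires
conditions outside this generator (e.g. asymmetric designs or
pseudo-replicated frozen series).

## Limitations

- No fitting of k_p to empirical responses; no nonlinear/multilayer
  decision classifier; no multi-step, seasonal or differenced forecasting
  variants; no ingestion of human-participant data.
- The ANOVA requires balanced, fully crossed tables — all the simulator
  produces — and does not implement unbalanced sums-of-squares variants.
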