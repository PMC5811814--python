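# adamsim

A seedable simulator of **adaptive anchoring** in one-shot judgmental
forecasting and average estimation from time series, together with the
baseline forecasting models it is usually compared against —
linear-regression next value, ARIMA(1,0,0), and simple exponential
smoothing — and the statistical harness (unrelated *t* tests with effect
size *r*, Levene's test, SD-ratio diagnostics, ε²-reporting factorial
ANOVA, split-half cross-validation) used to compare their predictions.

It is written for computational cognitive modelers and judgment-and-
decision-making researchers who want a reproducible, scriptable stand-in
for a behavioral time-series experiment: simulated observers view a
monthly salary series and give exactly two responses — a forecast of the
next value and an estimate of the series average.

## The model

An observer who experienced a series in presentation mode
*i* ∈ {static, historic-dynamic, momentary-dynamic} and is asked task
*k* ∈ {judgment of the average, forecast} responds

    BR_ik = SW_ik × EA_i × (1 + k_p · x_p),      SW_ik = exp(−(S_i − T_k)),

where

- *S_i* is an idealized stimulus item on [0, 1]: 0.35 (the normalized
  sequence mean) for static experience, the normalized last element for
  either dynamic mode;
- *T_k* is an idealized task item: 0.35 for average judgment, the
  normalized last element for forecasting;
- *EA_i* is an experience-dependent anchor in pounds: the sequence mean
  3,500 for static experience, the last presented value for dynamic
  experience;
- *SW_ik* is an exponential similarity weight on the **signed**
  stimulus–task distance (the sign carries the trend direction);
- *x_p* ~ N(0, 1) is perceptual noise scaled by the dimensionless
  coefficient *k_p* (default 0.04).

With *k_p* = 0 the model is deterministic and reproduces two classic
phenomena analytically: **trend damping** (static forecasts of a rising
trend fall short of the next trend value, falling trends are
over-predicted) and **anchoring of dynamic judgments on recency** (the
estimated average is dragged toward the last value).

Stimuli are 48-month salary series, Y(t) = 3000 + 21.28·t + n (rising),
Y(t) = 4000 − 21.28·t + n (falling), or Y(t) = 3500 + n (stationary),
with n ~ N(0, variance 10); *inconsistent* variants append a 49th value
of exactly 3,500, breaking the trend.

## Worked example

`adamsim demo` prints the deterministic decision-space table for the
zero-noise rising trend at *k_p* = 0:

```
Positive consistent trend, zero noise, kp = 0 (last element 4021.44):
mode               task             S        T       SW        EA        BR
---------------------------------------------------------------------------
static             judgment    0.3500   0.3500  1.00000   3500.00   3500.00
static             forecast    0.3500   0.4021  1.05353   3500.00   3687.35
historic_dynamic   judgment    0.4021   0.3500  0.94919   4021.44   3817.12
historic_dynamic   forecast    0.4021   0.4021  1.00000   4021.44   4021.44
momentary_dynamic  judgment    0.4021   0.3500  0.94919   4021.44   3817.12
momentary_dynamic  forecast    0.4021   0.4021  1.00000   4021.44   4021.44
```

Read the rows against the true next value 4,042.72 and the true mean
3,500: the static forecast (3,687.35) under-predicts the rising trend by
355 pounds while dynamic forecasts miss by only 21.28 (one month's
slope) — and the pattern flips for judgment, where the static estimate is
exact but dynamic estimates overshoot by 317. That fourfold dissociation
is the model's core behavioral claim. The two dynamic rows are identical
by construction: the model cannot distinguish historic from momentary
dynamic experience.

Simulation and model comparison from the shell:

```bash
adamsim simulate --n 90 --master-seed 1 --output-dir runs/       # full 3x3x2 design, both tasks
adamsim compare arima_100 exp_smoothing --master-seed 1 --output-dir runs/
# arima_100 vs exp_smoothing: t(3238) = 0.002, p = 0.9980, r = 0.000
```

The pooled null between ARIMA(1,0,0) and exponential smoothing is the
expected result: on strongly trended, low-noise series both track the
last observation, so their 1,620 one-step forecasts per model are nearly
interchangeable.

Or from Python:

```python
import numpy as np
from adamsim import AdamParams, run_full_design, summarize, estimate_kp

table = run_full_design(params=AdamParams(kp=0.04), n_per_condition=90,
                        models=("adam", "arima_100"), master_seed=1)
print(summarize(table).head())
print(estimate_kp(table))   # ~0.04: the perceptual-noise coefficient recovered
```

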