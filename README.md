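# alticycle

Haemoglobin, seasonal ecology and ovulation in menstrual-cycle cohorts at
high altitude.

`alticycle` is a reusable, tested pipeline for a reproductive-ecology
question: does iron status (haemoglobin) modulate a woman's investment in
reproduction — the occurrence of ovulation and the level of luteal
progesterone — and does that relationship depend on seasonal conditions?
It was built around a cohort of non-contracepting Aymara agropastoralists
living at ~3800 m on the Bolivian altiplano, where haemoglobin runs high as
an adaptation to hypoxia and the agricultural year splits into arduous
(harvest/planting) and better seasons, but every component is generic:
per-cycle hormone statistics, season/anaemia classification, multiple
imputation, and random-intercept mixed models.

## The statistics at its core

* **Mean peak luteal P4.** From every-other-day salivary progesterone
  samples, the cycle statistic is the mean of the linear interpolant over
  the ±2.5-day window around the observed luteal peak,
  `AUC(P4, x..y)/(y − x)` — robust to inter-cycle variation in peak timing.
  Ovulation is ascribed by thresholding this statistic (the threshold is an
  explicit config value).
* **Random-intercept mixed models**, implemented from first principles, for
  repeated cycles within women:
  `y_ij = x_ij'β + u_i + ε_ij` (gaussian, profiled ML) and
  `logit P(y_ij = 1 | u_i) = x_ij'β + u_i` (binomial, adaptive
  Gauss–Hermite quadrature — exact enough that the optimum log-likelihood
  matches direct numerical integration to ~1e-13 on toy fixtures).
* **Multiple imputation** of missing covariates by chained equations with
  predictive mean matching (m = 5, 10 iterations), pooled with Rubin's
  rules.
* **A synthetic study generator** with full ground truth (random
  intercepts, true ovulation flags, true effect sizes), so the whole
  pipeline is testable end-to-end without any data download.

See `docs/methods.md` for models, defaults, and numerical choices, and
`docs/dryad_mapping.md` for analysing the original study's deposited data.

## Worked example

```python
from alticycle import HormoneSeries, classify_ovulation, mean_peak_luteal_p4

days = [1, 3, 5, 7, 9, 11, 13, 15, 17, 19, 21, 23, 25, 27]
p4   = [48, 52, 45, 50, 55, 62, 85, 130, 190, 240, 255, 205, 130, 75]  # pmol/l
series = HormoneSeries.from_arrays(days, p4, cycle_length=28)

res = mean_peak_luteal_p4(series)
print(res.peak_day, res.mpl_p4, res.coverage_fraction)
print(classify_ovulation(res.mpl_p4, threshold=100.0))
```

prints

```
21.0 233.9375 1.0
1
```

— the observed peak falls on day 21, the mean interpolated P4 over days
18.5–23.5 is 233.9 pmol/l with the window fully covered by the observed
span, and the cycle is classified ovulatory at a 100 pmol/l threshold.

Running the full pipeline on a simulated cohort
(`python examples/05_mixed_models.py`) fits the two model families and
prints, for one seeded draw:

```
haemoglobin ~ season, random intercept by woman:
             estimate  ci_low  ci_high     se    p
(Intercept)    15.792  15.566   16.017  0.115  0.0
arduous        -0.914  -1.291   -0.536  0.193  0.0
predicted hb: arduous 14.88, better 15.79 g/dl

ovulation ~ hb_z (arduous seasons), logistic random intercept:
             estimate  ci_low  ci_high     se      p
hb_ard          2.675   1.274    5.619  0.379  0.009
```

— haemoglobin is ~0.9 g/dl lower in arduous seasons, and within arduous
seasons each SD of haemoglobin multiplies the odds of ovulation by ~2.7
(the generator's true odds ratio is 3), with no effect in better seasons.

The `examples/` directory has one short script per capability (simulation,
hormone statistics, seasons/anaemia, imputation + pooling, mixed models,
full pipeline). A thin CLI wraps the pipeline:

```bash
alticycle simulate --seed 11 --out simulated/
alticycle analyze --cycles simulated/cycles.csv --samples simulated/p4_samples.csv \
                  --config configs/study_config.yaml --out results/
```

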