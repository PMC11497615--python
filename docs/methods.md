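# Methods

`alticycle` re-implements, as a reusable and tested pipeline, an analysis
linking haemoglobin to ovulation and luteal progesterone among
non-contracepting women living on the Bolivian altiplano (~3800 m): per-cycle
hormone statistics, seasonal ecology classification, multiple imputation, and
random-intercept mixed models. This note records the models, the defaults
and their units, the numerical choices, and what the synthetic-data tests do
and do not demonstrate.

## Data model

The unit of analysis is a menstrual cycle. Each cycle carries one
haemoglobin measurement (g/dl) with its day of year, covariates (age,
breastfeeding status, household traditional-economy score, anthropometric
body-fat score), and an every-other-day salivary progesterone series
(pmol/l; day 1 = first day of menses). Women contribute 1–3 cycles, which is
why every model carries a per-woman random intercept. On disk a dataset is a
cycles CSV plus a long-format samples CSV; missing covariates are empty
cells, held as NaN in memory so imputation can see them.

## Mean peak luteal progesterone and ovulation

The cycle-level progesterone statistic is the mean concentration over the
±2.5-day span around the day of the observed luteal peak:

    mpl_P4 = AUC(P4, x..y) / (y − x),   x = t_peak − 2.5, y = t_peak + 2.5

with P4(t) the piecewise-linear interpolant of the observed samples and the
AUC evaluated exactly by the trapezoid rule after inserting knots at x and
y. Averaging around the observed peak is robust to inter-cycle variation in
the timing of the luteal rise, unlike statistics anchored to a fixed cycle
day.

Two boundaries the data do not define are configuration, not constants:

* **Luteal search window** — the follicular/luteal boundary is not
  observable from P4 sampling alone. Default: cycle midpoint
  (cycle_length/2) to the last observed sample; configurable.
* **Ovulation threshold** (pmol/l) on mpl_P4 — assay- and
  population-specific and published elsewhere; there is no in-code default.
  The bundled study config ships 100 pmol/l, labelled an assumption, sitting
  between anovulatory baseline (~50) and ovulatory luteal (~200+) salivary
  levels. A cycle is ovulatory iff mpl_P4 ≥ threshold (boundary inclusive).

When the ±2.5 d window exceeds the observed span it is clipped, never
rejected (every-other-day sampling makes edge peaks common); the result
reports the achieved `coverage_fraction` and is flagged unreliable below a
configurable floor (default 0.5). Peak ties break to the earliest day.

## Seasonal ecology

The agropastoral year (366 days, leap-year convention) partitions into
*arduous* seasons — harvesting (days 1–91) and planting (days 245–282), 129
days total — and *better* seasons (92–136, 137–244, 283–366; 237 days).
A cycle's season is that of its haemoglobin/anthropometry visit day, which
anchors the measured exposure.

Anaemia grading uses the altitude-adjusted threshold 14.6 g/dl. Only that
cut-off is published for this population; the severity bounds shipped
(mild ≥ 13.6, moderate ≥ 10.6, severe < 10.6 g/dl) apply the same +2.6 g/dl
altitude shift to the standard sea-level bands and are configuration with a
provenance note, not published values.

Haemoglobin is winsorized at the 5th/95th centiles of the analytic sample
(linear interpolation between order statistics, the "type 7" quantile rule;
the centile estimator itself is unstated upstream, so the rule is fixed and
documented here). Continuous covariates are z-scaled using the sample SD
(n−1). The body-fat score is the first principal component of
column-standardized anthropometrics, sign-oriented so weight loads
positively; with one retained component on standardized inputs this is the
deterministic near-equivalent of a one-factor maximum-likelihood analysis,
which is why PCA was chosen.

## Multiple imputation

Missing covariates (chiefly the traditional-economy score) are imputed m = 5
times by chained equations with predictive mean matching: initialize missing
cells from random observed draws; per sweep (10 sweeps), regress each
incomplete column on the others, and replace each missing cell with the
observed value of one of k = 5 donors nearest by predicted mean, chosen
uniformly. Chains are seeded `seed + chain` for reproducibility. The
conditional models are linear regressions (logistic predicted probabilities
would be the matching metric for a binary column); this deliberately differs
from random-forest PMM engines (e.g. missRanger) — the analysis-visible
contract is PMM semantics, m, and the iteration count, and a linear engine
is deterministic and dependency-light. Downstream estimates are pooled by
Rubin's rules:

    q̄ = mean(q_i),  W = mean(se_i²),  B = var(q_i),
    T = W + (1 + 1/m)·B,  df = (m−1)·(1 + W/((1+1/m)·B))²

with df = ∞ when B = 0 (then pooling reduces to the single-fit result).
Pooled inference uses the t distribution with these df.

## Mixed models

Both model families are implemented from first principles.

**Linear (haemoglobin; log mpl_P4):** y_ij = x_ij'β + u_i + ε_ij,
u_i ~ N(0, σ_u²), ε_ij ~ N(0, σ_e²), fitted by maximum likelihood (not
REML — ML supports likelihood comparisons and matches the estimation
defaults of the tooling this pipeline mirrors). The variance ratio
θ = σ_u²/σ_e² is profiled: β and σ_e² have closed GLS forms given θ, leaving
a 1-D bounded deterministic optimization on log θ (tolerance 1e-8 on the
profile objective; convergence verified by explicit local-optimality probes
rather than the optimizer's flag, which can report failure on very flat
profiles it has solved).

**Logistic (ovulation):** logit P(y_ij = 1 | u_i) = x_ij'β + u_i. The
per-woman marginal likelihood integral is evaluated by *adaptive*
Gauss–Hermite quadrature (default 15 nodes): nodes recentred at each group's
posterior mode (damped Newton on all groups at once) and rescaled by the
curvature there. With 1–3 cycles per woman a plain Laplace approximation is
noticeably inaccurate, which is why quadrature is the implemented
likelihood; on toy fixtures the optimum log-likelihood agrees with direct
numerical integration to ~1e-13. Optimization is L-BFGS-B on (β, log σ_u)
(tolerance 1e-8, max 500 iterations; β initialized from a plain logistic
fit, σ_u = 1), with a derivative-free Nelder–Mead polish when
finite-difference gradients abort the line search. If log σ_u reaches its
floor the model *is* plain logistic regression and β is recomputed exactly
by IRLS. Apparent complete separation is flagged as non-convergence, and
inference from unconverged fits is refused.

Inference is Wald throughout (normal CIs and two-sided p-values on the
estimation scale; odds-ratio tables exponentiate the estimate and CI
endpoints, keeping the SE on the log-odds scale). Standard errors come from
the numerically differentiated observed information (central differences,
relative step 1e-4). `predict_marginal` gives population-level predictions
at u = 0 — the conditional-mode convention, stated explicitly because the
population-averaged probability is attenuated by σ_u; covariate values are
always supplied explicitly by the caller.

## Pipeline

`run_model_suite` z-scales continuous covariates on the **full analytic
sample before stratifying**, so a coefficient means "per SD of the whole
sample" in every stratum and effects are comparable across strata
(per-stratum rescaling is available behind `scale_within_stratum`). Each
family is fitted crude and adjusted (haemoglobin models adjust for age; the
ovulation and progesterone models for age, body fat and breastfeeding), on
all cycles and separately on better- and arduous-season cycles. The
progesterone family models log mpl_P4 and uses ovulatory cycles only
(anovulatory cycles lack a corpus luteum; including them biases the
analysis). Fits are repeated per imputed dataset and Rubin-pooled; with no
missing covariates the suite fits once, which equals the B = 0 pooling path.
No multiple-testing correction is applied — a faithful-reproduction choice.
Any unconverged member fit fails its block loudly; there is no partial
pooling over failures. A plain residual/diagnostic plot export stands in for
simulation-based residual diagnostics, which are outside this contract.

## Synthetic-data generator

The generator emulates the study's statistical structure with known ground
truth: 96 women contributing 1/2/3 cycles (48/40/8 women; 152 cycles);
season drawn per cycle (P(arduous) = 34/152) *before* the visit day, which
is then uniform within the chosen season's calendar ranges (guaranteeing the
configured split in expectation at small n); haemoglobin

    hb = 15.7 − 0.76·arduous − 0.42·trad_z·arduous + u_i + ε,
    u_i ~ N(0, 0.8²), ε ~ N(0, 0.9²)   [g/dl]

(median ≈ 15.6 g/dl); ovulation from
logit p = 1.3 + log(3)·hb_z·arduous + u_i, u_i ~ N(0, 1) (ovulatory
fraction ≈ 0.76, with the haemoglobin effect in arduous seasons only); P4
profiles sampled every other day from a random start day 1 or 2 —
anovulatory: flat 50 pmol/l; ovulatory: a Gaussian luteal bump to
250 pmol/l, sd 6 days, centred 7 days before cycle end (the width chosen so
the noise-free ±2.5 d windowed mean of the every-other-day linear
interpolant stays within 5% of the peak: worst case 96.1% over cycle lengths
24–35 and both sampling starts) — under multiplicative log-normal noise with
CV 0.25 (assay concentrations are positive and right-skewed).
Traditional-economy scores are masked MCAR at rate 24/152. These magnitudes
are calibration targets of the generator chosen from the study's printed
descriptives, not facts about any real cohort.

**What the generator does not emulate:** conception and pregnancy loss,
lactational dynamics (breastfeeding is a Bernoulli covariate),
inflammation/iron-store mechanisms, assay batch effects, informative
missingness, and within-woman hb trends. Passing tests therefore show the
*pipeline* recovers the structure it assumes; they cannot show that real
data satisfy those assumptions.

## Verification and problem sizes

The statistical test surface, with the sizes the suite runs at:

* hormone statistic vs a dense (1e-4-cell) midpoint Riemann oracle on 1000
  random series: max relative error < 1e-6 (observed ~5e-9);
* GLMM optimum log-likelihood vs direct adaptive integration on 5-group
  toys, tolerance 1e-8; boundary collapse to plain logistic regression to
  1e-5; cross-checks against statsmodels MixedLM (5 LMM fixtures, β to 1e-3,
  σ_u to 1e-2) and R lme4::glmer with adaptive quadrature (2 GLMM fixtures);
* parameter recovery at study scale: fitting the generating model (crude
  arduous-slope GLMM) over 500 simulated studies recovers the true OR 3
  with |median bias| < 10% (long-run median bias ≈ +2%; 500 replicates keep
  the Monte Carlo error of the sample median near 2%). Fitting the same
  slope on the ~34-cycle arduous *subset* alone is a known small-sample
  failure mode — σ_u is unidentifiable from so few binary observations and
  diverges, inflating the slope (lme4 agrees to 3+ decimals) — and is
  documented as a limitation rather than used for recovery;
* type-I calibration: with all generator effects zeroed, the crude
  all-cycles fits of the three families reject at the 5% level at a rate in
  [0.01, 0.10] over 100 replicates (observed ≈ 0.03–0.06; Wald tests in
  small clustered samples run slightly conservative here);
* PMM membership (imputed cells always equal observed donor values), the
  Rubin worked example, and the zero-missingness fixed point.

## Reference values requiring the original data

The published regression estimates this pipeline is shaped around (seasonal
hb gap 0.76 g/dl; trad-econ arduous slope −0.42; ovulation ORs 2.59 crude /
3.27 adjusted in arduous seasons; predicted seasonal means 14.85/15.61 g/dl;
median hb 15.6; winsorize caps 11.8/17.5 g/dl) are **not** reproducible from
synthetic data — they require the original deposit (Dryad
doi:10.5061/dryad.tqjq2bw7f) and its exact imputation stream. They are
recorded in `alticycle.pipeline.DRYAD_REFERENCE_TARGETS` with a mapping
recipe in `docs/dryad_mapping.md` for users who obtain the data; the
property-based surface above is what this package's tests assert.

## Known limitations

* Wald (not profile-likelihood) intervals throughout; slightly conservative
  in small strata.
* Single random intercept only: no random slopes, crossed effects, or
  multilevel imputation models.
* The arduous-stratum GLMM on ~34 cycles is fragile in *any* ML
  implementation (σ_u divergence); season-stratified odds ratios from small
  strata should be read alongside the full-sample interaction fit.
* The ovulation threshold and anaemia severity bounds are documented
  assumptions; substitute published, assay-specific values for real
  analyses.
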