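# Methods

## The model

`micromi` is an agent-based microsimulation of myocardial infarction (MI)
in a closed cohort, built so that population-level incidence, event and
prevalence rates are *endogenous*: they emerge from individual risk-factor
levels, secular trends in those factors, and a declining 30-day case
fatality, never from extrapolated disease-rate series.  Each agent carries
sex, age, three continuous risk factors (BMI in kg/m², systolic blood
pressure in mmHg, total cholesterol in mmol/L), three binary factors
(current smoking, diabetes, prior MI), vital status and MI history.

Agents are simulated over annual time points from a 1998 baseline to a
2035 horizon.  Within each event year, in fixed order:

1. an MI event is drawn with probability `p = 1 − exp(−h)`, where the
   hazard is multiplicative log-linear,

   `h = baseline_scale · h₀(sex, age) · RR_bmi^((bmi−22)/5) ·
   RR_sbp^((sbp−115)/10) · RR_chol^(chol−3.8) · RR_smoke^[smoker] ·
   RR_diab^[diabetic] · RR_prior^[prior MI]`;

2. if an MI occurred, 30-day death is drawn from a case-fatality
   probability that is logistic in age around 70 (fixed female log-odds
   offset of +0.20, not calibrated) and declines geometrically in
   calendar year at rate `cf_trend`;
3. other-cause death is drawn from an exogenous life table indexed by
   sex, age and calendar year;
4. survivors get one year of risk-factor trends, `prior_mi` is set if an
   MI occurred, and age increments.

The event order (MI → case fatality → other death → update) is a
convention, stated because it shifts rates at the third decimal: it makes
MI deaths and other deaths disjoint and keeps every MI event countable.
The baseline hazard schedule `h₀` never changes over calendar time; all
temporal change comes through risk factors and case fatality.

Risk-factor dynamics: BMI approaches an asymptote geometrically
(`bmi ← bmi + rate·(asymptote − bmi)`); SBP and cholesterol drift
linearly; smoking can only be quit (annual probability
`trend_smoking_quit`) and diabetes only acquired (age-exponential
incidence scaled by `trend_diabetes_inc`) — one-way transitions that
preserve within-person autocorrelation.  Continuous factors are clamped
to plausible ranges (BMI 14–60, SBP 80–230, cholesterol 2–12).

Non-MI mortality is independent of risk factors by design.  This is a
deliberate simplification: high-risk agents survive longer than they
would in reality, which biases MI prevalence upward in high-risk strata.

## Randomness and reproducibility

All stochastic resolution uses counter-based (Philox) uniform draws keyed
by `(seed, agent id, year, draw slot)` with a fixed five-draw layout per
agent-year.  Results are therefore invariant to agent processing order
and to any parallel decomposition, and identical seeds give byte-identical
event logs.  Seeds for batches of runs are derived through
`numpy.random.SeedSequence` and kept below 2³¹.

## Outputs

Per (year, sex, age group ∈ {55–64, 65–74, 75–84, 85+}):

* **incidence** — first MI events per 100,000 agents alive and MI-free at
  the start of the year (the standard at-risk denominator);
* **event rate** — all MI events per 100,000 agents alive at the start of
  the year;
* **prevalence** — proportion of agents alive at the end of the year who
  have ever had an MI, grouped by attained age.

Denominator anchors (start-of-year for incidence/event, end-of-year for
prevalence) are fixed conventions; they matter in high-mortality strata.
Agents killed by their MI within the year still count in the incidence
and event numerators, consistent with event data assembled from hospital
episodes plus death certificates.  Note that because incidence uses the
MI-free subset while event rates use all alive, `incidence ≤ event rate`
holds as a count identity (first events ⊆ all events) but the *rate*
inequality can fail in small strata with high prior-MI prevalence; the
test suite checks the count identity, which is exact.

Age-standardised rates are direct: `Σ_g w_g · rate_g` with non-negative
weights summing to 1 (default weights are a synthetic stand-in for a
2018 national over-55 structure: 0.39/0.33/0.20/0.08).  Ensemble
uncertainty bands are empirical 2.5th–97.5th percentiles with linear
interpolation between order statistics (the `numpy.quantile` default).

## Calibration by history matching

Three classes of parameters are calibrated: relative risks, risk-factor
trend parameters, and the case-fatality level/trend (16 parameters,
independent uniform priors; see `micromi.params.default_priors`).  The
calibration loop per wave:

1. run the simulator at a batch of parameter vectors (wave 1: Latin
   hypercube over the prior box; later waves: resampled from the
   previous retained set);
2. fit one emulator per calibration output — by default linear regression
   on a full quadratic basis of parameters standardised to [−1, 1] over
   the prior box, with predictive variance `σ̂²(1 + leverage)`; a
   Gaussian-process backend is selectable;
3. screen a large candidate sample with the implausibility
   `I(θ) = |m(θ) − z| / √(v(θ) + v_obs)`, retaining vectors with
   `max_targets I ≤ 3` (the three-sigma rule);
4. stop when the retained proportion of the prior space (the running
   product of per-wave conditional retention) changes by <10% relatively,
   or at the wave cap; then sample the forecast ensemble uniformly from
   the final retained set (with replacement if it is smaller).

Targets whose held-out emulator correlation falls below a floor
(default 0.5) are excluded from the implausibility maximum for that
wave.  In practice this down-weights incidence cells — which are
count-sparse and hence noisy — relative to prevalence and event rates,
and is the mechanism by which calibration leans on the outputs the
emulator reproduces reliably.

Monte-Carlo noise in training responses is absorbed by the emulator's
residual variance rather than replicate runs.  The emulator refuses to
extrapolate outside its box; for screening, the box is the prior box
(`fit_emulator(..., box=priors)`), since design min/max margins would
spuriously reject boundary candidates.

## The synthetic-data generator

No real hospital-episode, death-registration or health-survey data ship
with the package.  The generator produces:

* a baseline cohort spanning ages 18–100 (younger adults must exist in
  1998 to enter the over-55 output window by 2035), with banded age-sex
  demography and truncated-normal/Bernoulli risk factors whose age
  gradients follow national health-examination surveys of the period;
  baseline prior-MI prevalence rises to 20% in 85+ men, half that in
  women;
* a Gompertz-like non-MI life table with a constant annual improvement
  rate (default 1%/year);
* calibration targets from a single simulator run at a known parameter
  vector: incidence and event rates annually over 1999–2011, prevalence
  at survey-style years (2003, 2005, 2006, 2011), with independent
  Gaussian noise (default SD: 5% of the value with floors of 20 per
  100,000 / 0.002).  The recorded observation variance is the injected
  noise variance *plus* the finite-sample (binomial/Poisson) variance of
  the generating run's own rate estimate — a target built from a finite
  cohort carries that sampling error exactly as real registry and survey
  estimates carry theirs, and omitting it makes the implausibility
  denominator overconfident.

The generator emulates the *shape* of the real calibration data (age
gradients, secular decline, survey timing, observation error), not any
real population: no migration or births, no ethnicity or deprivation
structure, no cohort effects, and non-MI mortality that ignores risk
factors.  Passing tests therefore demonstrate that the machinery —
simulation, emulation, screening, recovery — works as specified, not
that any specific national forecast is correct.

## Baseline schedule defaults

The default first-MI hazard at reference factor levels is exponential in
age (doubling every 8 years), anchored at 0.15%/year for men at age 70,
plateauing at age 90, women at half the male hazard.  Typical elderly
risk-factor profiles carry multiplicative relative risks of ~4–6 above
the reference anchor (BMI 22, SBP 115, cholesterol 3.8), so effective
incidence lands at observed magnitudes (hundreds to a few thousand per
100,000, prevalence of order 5–25% in the over-65s).  `baseline_scale`
is calibrated, so the anchor is a convenience.  An earlier sketch of
1%/year at 70 doubled every 7 years produces 85+ prevalence of 40–60%
once the relative risks are applied — outside any realistic range —
which is why the anchor refers to reference levels, not typical ones.

## Problem sizes

Two named budget profiles: `desk` (5,000 agents, 120 runs/wave, 100,000
candidates/wave, ≤3 waves) for tests, examples and the acceptance
script, and `full` (114,000 agents, 450 runs/wave, 2,000,000
candidates/wave) for production-scale studies.  The desk-scale recovery
study calibrates four influential parameters (`baseline_scale`,
`rr_smoking`, `cf_base`, `trend_sbp_slope`) with the rest held at their
generating values via degenerate priors: a full quadratic basis in 16
parameters needs 153 coefficients, more than 120 runs per wave can
support, and four parameters give a well-posed recovery problem at this
budget.  The forecast ensemble is 450 runs in both profiles, each with a
fresh simulation seed so the uncertainty bands include Monte-Carlo
variability.

## Known limitations

* Emulator held-out correlations at desk scale are capped by a binomial
  noise ceiling in small strata (e.g. 85+ cells have denominators of a
  few dozen at 5,000 agents); correlations approach the ceiling, and the
  ceiling itself rises roughly as √n_agents.
* The quadratic emulator cannot represent strong non-monotone
  interactions; the GP backend is available where that matters.
* Implausibility uses observation variance only — no structured model
  discrepancy term.
* Single disease, single binary smoking state, no sub-annual timing, no
  migration or births.
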