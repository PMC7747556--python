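# Methods

This note documents the statistical machinery implemented in `actiflm`, the
choices that were genuinely open, and what the synthetic-data validation does
and does not establish.

## Data model

The atomic observation is an epoch count: a nonnegative integer summarising
gross motor activity over one fixed window (1 min by default) from a
collar-mounted accelerometer. A subject's record is a strictly regular epoch
grid with an explicit missingness mask; collar-off time is *missing*, never
zero, because a zero is an observation of stillness while a masked epoch is
no observation at all. Gaps in an ingested CSV's timestamp grid are filled
with missing-marked epochs; non-monotone or duplicated timestamps are hard
errors rather than silent repairs.

Clock arithmetic is done on minutes-since-midnight integers with half-open
intervals throughout. A night belongs to the calendar date its bedtime falls
on, so post-midnight epochs are attributed to the previous date's night; a
date's daytime stratum is its complement (waketime to bedtime of the same
date). When the diary lacks a window for a date, a 22:00–07:00 default is
applied with a logged warning. Weekend means Saturday/Sunday.

## Smoothing

Each subject's multi-day record is collapsed to a 1440-point diurnal profile
(per-clock-minute mean over non-missing days) and projected onto the
truncated Fourier basis {1, cos(2πkt/1440), sin(2πkt/1440)}, k = 1..K, by
ordinary least squares over the observed minutes. Defaults and rationale:

- **K = 9 harmonics (19 coefficients).** Enough to represent a bimodal
  diurnal shape with ~1.5-h peaks without chasing minute-level noise; the
  basis's temporal resolution is roughly 24 h / (2K + 1) ≈ 75 min. K is a
  configuration knob, and the residual-SSE-vs-K curve (monotone by nesting)
  is the sensitivity diagnostic.
- **Missing minutes are excluded, not imputed**; the periodic basis
  interpolates through gaps. Fitting requires at least 2K + 1 observed
  minutes.
- **No roughness penalty.** The fit is a plain linear projection, which
  buys exact idempotence and nested-monotone residuals; penalized variants
  are future work.
- Evaluated curves may dip below zero between observations; raw evaluations
  are kept for inference and only plotting clips at zero.

## Pointwise permutation FLM

At every grid minute the smoothed curve values are regressed on a
subject-level design; the covariate under test contributes a q-df F
statistic F(t) = [(SSE₀−SSE₁)/q]/[SSE₁/(n−p)]. Conventions:

- **Permutation unit = the whole subject curve.** Subjects are exchangeable
  under the null of no covariate effect; permuting within curves or days
  would destroy temporal dependence and is never done.
- **The observed assignment is included as the first permutation.** This
  bounds the pointwise p below by 1/n_permutations and makes the per-point
  rejection probability exactly α: with B permutations the critical value is
  the ⌈(1−α)B⌉-th order statistic and rejection (strict >) happens exactly
  when the observed F ranks in the top ⌊αB⌋.
- **Critical curve:** empirical order-statistic quantile per minute;
  **p-curve:** proportion of permutation F values ≥ the observed.
- In a multi-covariate design only the tested column is permuted against
  the rest by default (simple permutation; full-design permutation is a
  config option). The default analysis tests one covariate at a time.
- Zero residual variance at a point reports F = +inf with a warning;
  SSE comparisons use a relative tolerance of 1e−20 on the response's
  sum of squares so floating-noise residuals do not masquerade as signal.
- Significant minutes are merged into maximal runs that wrap midnight and
  reported as clock intervals.

## Day/night mixed models and model averaging

Per-day stratum means (over non-missing epochs) are log(x+1)-transformed and
modelled with a per-subject random intercept. Choices:

- **log offset = 1 count**, because zero-activity night strata occur.
- **A stratum-day is dropped when more than half of its *expected* epochs
  are unobserved** — masked or simply outside the recording. Using the
  expected window length as the denominator matters at the record
  boundaries: a final night clipped to its first (quiet) 90 minutes would
  otherwise enter as a severely biased mean, and a biased edge night landing
  on a weekend date is enough to fabricate a day-type effect in the night
  model.
- **ML, not REML**, for every fit: REML log-likelihoods are not comparable
  across fixed-effect sets, and the whole point is AIC ranking. AIC counts
  k = (#fixed incl. intercept) + 2 (random-intercept and residual
  variances). A boundary fit (intercept variance ≈ 0) is flagged, not
  raised, and its fixed effects coincide with OLS.
- **All 2⁴ subsets** of {day type, age, sex, mass} are candidates; models
  with ΔAIC < 10 are retained; Akaike weights renormalize over the retained
  set.
- **Conditional (natural) averaging**: each term is averaged over retained
  models containing it with renormalized weights; the unconditional SE is
  √Σ w(se² + (β−β̄)²), which includes between-model spread. The full
  (zero-substituted) average is also reported alongside. z and p use the
  standard normal; CI95 = estimate ± 1.96·SE.
- Continuous predictors are z-scored (per modelling table) for the reported
  standardized estimates; AIC ordering is invariant to this reparametrization.

Conditional averaging is known to be mildly anti-conservative for weak
terms (the conditional estimate is biased away from zero), which shows up in
the coverage study below as per-term coverages a point or two either side of
nominal.

## The synthetic cohort generator

The generator is the ground-truth engine for every validation: 42 dogs × 14
days × 1440 one-minute epochs by default, starting on a Monday (10 weekdays,
4 weekend days).

- **Diurnal template:** two circular-Gaussian (von Mises) bumps at 07:00 and
  19:00 (SD 1.5 h, height 180 counts/epoch) over a day/night step baseline
  (60 day / 8 night, night 22:00–07:00): a bimodal day with a midday trough
  that stays above the overnight level.
- **Covariates:** age ~ U(2, 9) y, mass ~ U(2.7, 45.4) kg, sex exactly
  balanced. Per-dog bedtime ~ U(22:00, 23:00) and waketime ~ U(06:00,
  08:00), jittered ±30 min per night into the diary; the simulated
  physiology follows the diary nights exactly, and the diary starts the
  evening before recording so the first morning is covered.
- **Between-dog variability** has three parts, all on the log rate:
  a scalar level (SD 0.2), a smooth random shape — 9 independent Fourier
  harmonics, SD 0.15 each (pointwise SD ≈ 0.45) — and a nighttime
  restlessness level (SD 0.5) applied inside the dog's own nights. The split
  is deliberately pattern-dominated: dogs differ far more in *when* they are
  active than in total amount, and overnight movement varies widely between
  individuals. A purely scalar level would make all curves proportional, in
  which case every pointwise F statistic collapses onto a single number and
  pointwise inference degenerates.
- **Covariate effects** multiply the log rate inside configured clock
  windows (defaults: age −0.05/y in 07:00–10:00 and 17:30–21:00, sex −0.15
  for males in 18:00–22:00, mass −0.004/kg in 00:00–01:00), with covariates
  centred at fixed anchors (age 5.5 y, mass 24.05 kg) so the count scale
  does not drift with cohort composition. Effects can be box-shaped or
  raised-cosine tapered (45-min edges); tapered is what a biological effect
  looks like, and a discontinuous effect pushed through a truncated Fourier
  smoother rings far outside its window.
- **Counts:** negative binomial with mean = template × exp(all log terms)
  and size 2 (variance μ + μ²/2), the canonical overdispersed count model.
  Real collar counts vary in dispersion by device and animal, so this
  default is a placeholder exposed in config.
- **Weekends** multiply the daytime (non-night) rate by 1.25.
- **Collar-off gaps** (optional) mask whole days or 2–6-h spans; masked
  epochs keep their drawn counts but are flagged missing.
- Generation is a pure function of (config, seed); identical seeds give
  byte-identical CSVs.

What the generator does *not* emulate: raw tri-axial accelerations and count
firmware, autocorrelated within-day behaviour (bouts, naps), day-to-day
pattern changes within a dog beyond the independent NB noise, seasonal or
weather effects, and household covariates. Passing tests therefore show the
*inference machinery* is correct and calibrated under a realistic count
model — not that any particular real cohort satisfies these assumptions.

## Validation studies and problem sizes

`actiflm.experiments` packages three replicated studies, which the
acceptance tests run at these sizes:

- **Null calibration:** 20 cohorts × 40 dogs, no injected effects, sex test
  with 500 permutations on a 144-point (10-min) grid. Mean significant
  fraction ≈ α = 0.05 (exactly α per point by construction; the replicate
  mean carries Monte-Carlo spread ≈ 0.01 because nearby minutes are
  correlated through the 19-dimensional smoothing basis).
- **Effect-window recovery:** a strong tapered age effect (−0.25/y) in the
  two peak windows, 42 dogs, full 1440-min grid, 500 permutations, averaged
  over 10 replicate cohorts (a single cohort's outside-window fraction has
  SD ≈ 5% through between-dog curve dependence, so one draw is a poor
  measurement of localization). Measured: ≈ 87–92% of injected-window
  minutes significant, ≈ 6–9% outside.
- **Averaging coverage:** 100 replicate summary tables at 42 × 14 drawn from
  the mixed-model generative process itself (daytime truth 0.25 weekend,
  −0.30 age, −0.23 sex standardized; nighttime all zero). Mean 95%-CI
  coverage per stratum ≈ 0.92–0.93.

The acceptance script (`scripts/acceptance.py`) recomputes the first study
from scratch under a caller-supplied seed.

## Known limitations

- Pointwise inference controls the per-minute error rate only; no
  familywise or FDR control across minutes is attempted (a max-F global
  band would be the natural extension).
- The Fourier basis imposes ≈ 75-min resolution at K = 9; effects narrower
  than that blur across their window edges, and effect leakage from
  high-activity periods can reach low-activity periods when between-dog
  variance there is small.
- Conditional model averaging's coverage is approximate for weak terms.
- The day/night response is the per-day mean over non-missing epochs, not
  the daily total; the two differ only by a day-length factor absorbed into
  the intercept unless missingness varies systematically.
- Night windows rely on owner-reported bedtimes; no attempt is made to infer
  sleep onset from the counts themselves.
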