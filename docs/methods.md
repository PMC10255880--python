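# Methods

This note documents the models, the synthetic-data generators, the
numerical choices, and the limits of what the tests demonstrate.

## Event model and quality control

The unit of raw input is a *stepping event*: a contiguous bout with a
participant, device (`thigh` or `wrist`), start timestamp, duration in
seconds, and step count. Cadence (steps/min) is always derived as
`steps / (duration_s / 60)` and never stored, so it cannot drift out of
sync with its inputs.

Quality filters, applied in a fixed order so every removed event is
counted under exactly one rule:

1. fewer than 10 steps (too short for a reliable cadence);
2. cadence below 20 steps/min (the thigh reference system does not
   report below this, so both devices are truncated identically);
3. cadence above 175 steps/min (same reasoning at the top end);
4. events starting after a participant's first 7 distinct calendar
   days (guards against over-weighting cyclical weekly behaviour).

Boundary cadences of exactly 20 or 175 steps/min are kept. The
first-days window counts any date with an event *or* a wear record, in
chronological order. Events are assigned to the calendar date of their
start time; events spanning midnight are not split — no splitting rule
is defensible at daily resolution and the bias is negligible.

Validity rules are profile parameters, not hard-coded: a paired-study
day is valid when *both* devices were worn ≥ 20 h (inclusive); a cohort
recording period is valid with ≥ 6 days of ≥ 18 h wear. Wear hours are
taken as given input; upstream non-wear detection is out of scope.

## Cadence bands and the biomarker

Total steps (20–175 steps/min) split into non-walking `[20, 45)` and
walking `[45, 175]`. Walking splits at the **median walking cadence**:
the unweighted median (one vote per event, pooled over participants,
days, and periods) of cadences ≥ 45 steps/min. Each measurement system
gets its own median because systems segment events differently; the
split uses the exact, unrounded median — rounding first would reassign
boundary events — with "slower" meaning cadence ≤ median. Slower-paced
steps = non-walking + slower-paced walking, so (slower-paced,
faster-paced walking) partitions the daily total exactly.

For multi-period cohort data the pooled median is computed over all
periods by default; a baseline-only median is a flag away
(`median_walking_cadence` simply receives the subset). Whether pooling
is the right choice is genuinely open; pooling keeps the band
definition constant over follow-up, which is what a longitudinal
coefficient per band requires.

The biomarker renders the two period-mean components as integers,
rounding half-up; if the rounded parts miss the rounded total by ±1 the
larger component absorbs the difference, so the printed pair always
sums to the printed mean total.

## Agreement: variance-components CCC

Paired daily totals are modelled as
`y_ijk = μ + β_j + α_i + (αγ)_ik + (αβ)_ij + ε_ijk` with random
participant, participant-day (shared between devices), and
participant-device effects, and a fixed device offset. Concordance is

```
CCC = (σ²_α + σ²_αγ) / (σ²_α + σ²_αγ + σ²_αβ + s²_β + σ²_ε),  s²_β = (β_wrist − β_thigh)² / 2.
```

Participant and participant-day variation is shared by both devices and
therefore concordant; device-linked variation and noise are not.

Estimation is restricted-likelihood. For *balanced* panels (every
participant, both devices, equal day counts) the REML solution is
available in closed form through the balanced ANOVA mean squares, and
the package uses it directly; unbalanced panels fall back to numerical
REML (statsmodels `MixedLM` with the same structure). The two routes
are cross-checked against each other in the tests, and against Lin's
moment CCC in the single-replicate case. Negative component estimates
are truncated at zero — this keeps the CCC in range, at the price of a
small upward bias when a true component is 0 and of making the
estimator non-negative, so a no-agreement dataset yields an interval
whose lower edge sits at ~0 rather than straddling it. With one day
per participant both interaction terms are confounded with the residual
and are dropped automatically. If the subject-day variance lands on the
boundary it is reported as 0 but the term is not removed, keeping the
CCC formula's terms defined across bands.

Confidence intervals are 95% percentile cluster bootstraps: resample
participants with replacement (each draw becomes a new cluster), refit,
take percentiles; 500 replicates by default, deterministic per seed.
Asymptotic variance-component standard errors are fragile at n ≈ 56
participants, and the bootstrap needs no extra derivatives. Balanced
resamples reuse the closed form, which makes the bootstrap effectively
free; unbalanced resamples refit numerically and a replicate-failure
rate above 20% is recorded as a warning on the result.

## Longitudinal association with physical function

SPPB (integer 0–12) at months 0/6/12/24 is modelled with a random
intercept per participant and fixed effects for: time (categorical,
baseline reference), trial-arm allocation and allocation × time, age,
sex, site, perceived health (SF-36 class), comorbidity, IMD quintile
(categorical), education, the stepping term(s) scaled to 1000
steps/day, and stepping × time. The three variants: Model 1 total
steps; Model 2 faster-paced walking steps; Model 3 faster-paced walking
plus slower-paced steps — two non-overlapping bands whose sum is the
total, which keeps collinearity low and the coefficients interpretable.

A follow-up stepping coefficient is the interaction contrast; the total
association at time *t* is baseline + contrast, exposed as
`total_effect`. Inference uses the large-sample normal approximation
(CIs as estimate ± 1.96 SE). Coefficients come from REML fits; AIC and
log-likelihood from full-likelihood refits, because restricted
likelihoods are not comparable across different fixed-effect sets. Age
enters linearly (the open alternative, age bands, costs degrees of
freedom without an obvious gain at n ≈ 650). Participants need ≥ 2
valid periods; missing covariates are handled complete-case. Rank
deficiency (e.g. an empty allocation × time cell) is detected by QR
with pivoting before fitting and reported with the aliased column
names. Optimisation retries a ladder of optimizers (lbfgs → cg →
powell → nm) before declaring non-convergence.

Scenario projections are plain arithmetic:
`Δslower·θ_slower + Δfaster·θ_faster` in thousands of steps/day,
rounded half-away-from-zero at 2 decimals. Sensitivity refits drop the
health/socio-economic covariates and stratify by allocation; strata too
small or degenerate to fit are reported as skipped with the reason.
A mixed-effects ordinal (cumulative-link) replication is deliberately
not implemented; the linear treatment of the 12-point score is the
primary analysis and the ordinal check would need a fitter outside this
package's dependency set.

## Synthetic studies: what they emulate, what they don't

**Paired agreement study** (default: 56 participants × 7 days × 2
devices). Latent daily totals follow the same crossed random-effects
decomposition the agreement model estimates, with defaults
(σ²_α, σ²_αγ, σ²_αβ, σ²_ε) = (13.0, 9.6, 0.3, 2.1) × 10⁶ steps², a
thigh mean of 9065 steps/day and a wrist offset of +656 — participant
(~51%) and day-to-day (~38%) variation dominate and the devices
contribute little, with an implied total-steps CCC ≈ 0.90. Each latent
total is decomposed into events whose step counts sum to it *exactly*
(conservation is a tested invariant): per-band step budgets from a
Dirichlet draw around configured shares (non-walking 38%, slower
walking 26%, faster walking 36%), per-event step counts log-normal with
a 10-step floor, cadences truncated log-normal per band, and a +2
steps/min wrist cadence shift so the two systems' median walking
cadences differ as different processing pipelines do. Invalid events
(< 10 steps, out-of-range cadences) and sub-threshold wear days are
injected on top at configurable rates so the filters and validity rules
have real work; they never contribute to the latent totals. A
daily-totals-only entry point (`simulate_paired_daily`) skips event
synthesis for simulation studies of the agreement model itself.

Not emulated: raw tri-axial signals, gait mechanics, within-day
activity rhythms, device-specific step-detection error that varies with
cadence (the event distributions are a stylised free-living shape, not
fitted to any dataset).

**Longitudinal cohort** (default: 651 participants, periods 0/6/12/24
months). Per-band participant-period stepping levels are gamma variates
whose means and SDs match the configured period targets exactly
(defaults decline over follow-up: total 5815 → 4871 steps/day), linked
by a Gaussian copula with a stable participant component (65% of latent
variance) and a common activity factor (r = 0.6) that correlates the
bands within person. Gamma margins matter: stepping is right-skewed
with SD ≈ mean in the faster band, and a clipped normal would inflate
the means. Day-level counts vary around the period level with
gamma noise (CV 0.30), and wear hours occasionally fall below
threshold, so period validity and two-stage aggregation are exercised
for real. SPPB is generated as a linear predictor — covariate effects,
per-period stepping coefficients applied to the *realised* mean
stepping over that period's valid days, a participant random intercept
(σ² = 1.0), residual (σ² = 0.81) — rounded to an integer and clipped
to [0, 12]. The stepping coefficients are specified as total effects
per period (slower-paced {0.03, 0.07, 0.09, 0.16}; faster-paced
{0.05, 0.27, 0.40, 0.58} SPPB per 1000 steps/day), so the fitted
24-month interaction contrasts target 0.13 and 0.53. The intercept
(7.0, baseline mean ≈ 6.6) deliberately places the cohort where the
score ceiling almost never binds: the outcome model is linear by
construction, and pushing the mean toward the ceiling compresses the
high-stepping tail and attenuates precisely the coefficients the
recovery tests measure. Covariate prevalences follow a realistic
older-trial population (two-thirds female, mean age 77); per-period
missingness (6.6%→22.6%) thins follow-up as attrition does.

Not emulated: informative missingness (dropout is independent of SPPB
and stepping), SPPB's ordinal subtest structure, measurement error in
stepping relative to true behaviour, practice effects in the physical
tests. Passing recovery tests therefore shows the estimators are
correct for data meeting the stated model assumptions — not that the
assumptions hold in any real cohort.

## Numerical and reporting choices

* All randomness flows from one integer seed per run
  (`numpy.random.default_rng`); identical config + seed reproduces
  every output byte for byte, and the pipeline manifest records the
  config hash, seed, and package versions.
* Rounding: biomarker components and integer percentages round
  half-up; scenario projections half-away-from-zero; the walking split
  uses the unrounded median.
* Degenerate inputs: constant data yield CCC = 1 (all pairs identical)
  with the subject share defined as 1; an empty event table filters to
  an empty table; a zero baseline makes a percent change undefined and
  flagged rather than infinite.
* Simulation study sizes in the test suite (50 agreement recoveries,
  200 reduced-scale bootstrap-coverage studies at 40 × 5, 100
  full-scale cohort recoveries, 200 null cohorts at n = 250) were
  chosen to put Monte-Carlo error comfortably inside the asserted
  tolerances.

## Known limitations

* The bootstrap CCC interval is percentile-based; it inherits the
  usual small-n percentile biases and is not expected to match any
  particular closed-form interval.
* The balanced/unbalanced estimation split means a single dropped day
  switches the estimator from closed-form to numerical REML; estimates
  agree to optimizer tolerance, but runtimes differ sharply (the
  numerical bootstrap is ~100× slower).
* Vendor export adapters are configurable column maps, not faithful
  parsers of any proprietary report format.
* The cohort generator produces banded daily counts directly; the
  event-level path (median cadence, banding) is exercised by the paired
  profile only.
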