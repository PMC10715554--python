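# Methods

## Problem and data model

The unit of observation is an attended screening episode: person id, calendar
date, and per-eye retinopathy/maculopathy grades on the UK NSC scale (R0, R1,
R2, R3, R3S, U × M0, M1, U). Analysis is person-level on the worst eye:
STDR is any R2/R3 or M1; PDR is any R3; an episode with any U component is
ungradable as a whole and its disease flags are undefined by convention —
the analysis excludes such episodes before baseline and censors at them
afterwards, even when the fellow eye shows disease. This is the stricter of
the two defensible readings (the alternative — grade on the gradable eye —
would keep a handful of extra episodes) and matches the blanket exclusion of
ungradable images in programme practice.

Elapsed time is computed in days and converted with 1 year = 365.25 days and
1 month = 365.25/12 days; the 14-month cycle rule needs a fixed day
equivalent.

## Cohort construction

Baseline is the second episode of the earliest pair of successive attended
episodes that are both fully gradable R0M0, with an inter-episode gap inside
a configurable window (default 0.5–1.5 years; "consecutive annual" is not a
precise quantity in programme data, so the window is a parameter, not a
constant). Using the earliest qualifying pair maximises follow-up. Anyone
with STDR or stable treated PDR (R3S) at or before the candidate baseline is
excluded. The cascade — identified → attended → complete demographics →
qualifying pair → no prior STDR/R3S — is reported with counts at each step.

Follow-up ends at the first post-baseline episode that is not a clean R0M0:
STDR presentation (event), ungradable (censor), any other retinopathy
(censor). Censoring at R1 is permanent by default: a later STDR is not
counted. The censoring sentence that defines the outcome supports this
literal reading, but it is genuinely ambiguous, so
`EligibilityRules(censor_at_first_dr=False)` switches to the alternative in
which R1 episodes are ignored and later STDR counts. People with no
post-baseline episode are retained with zero person-years: they enter
per-person denominators but never contribute events.

## Synthetic registry

The generator's defaults are the study conditions the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| demographic mixture | 37% white / 36% South Asian / 16% black / 5.8% other Asian / 2.8% other / 1.2% mixed / 0.7% Chinese / 0.8% unknown; 48/52 sex; 20/24/25/31 age bands; 95/2.6/0.2/1.8 diabetes type; 11/32/29/19/9.9 IMD | baseline covariate distribution (normalised) |
| `overall_rate_target` | 0.0051 /person-year | marginal STDR hazard; λ0 is solved from it |
| `log_hr` | age 0.70/0.54/0.70; male 0.96; ethnicity 1.54/2.21/1.39/1.86/2.07/0.63/1.91; type 1 1.41, other 1.83, unknown 1.35; IMD 1.16/1.06/1.08/1.12; duration 1.26 per 5 y | proportional-hazards truth |
| `lambda_r1` | 0.05 /person-year | hazard of non-referable R1M0; no published value exists — chosen so a realistic minority (~15–20%) of the no-DR cohort censors via R1; a placeholder, and configurable |
| `p_pdr_given_stdr` | 103/1788 | probability an incident STDR presentation is proliferative |
| visit gaps | log-normal, median 1.0 y, IQR width 0.2 y | annual recall with late attendance |
| `never_attend_prob` | 0.108 | fraction offered but never screened |
| `u_grade_prob` | 0.001 | per-episode ungradable probability |
| study window | 2012-01-03 to 2021-12-31, 8-year follow-up cap | staggered uniform entry |

Calibration is analytic: λ0 = target / E[exp(x'β)], where the expectation
factorises over the independently sampled covariate dimensions and the
duration term uses the truncated-normal moment generating function. The
latent model is two independent exponential clocks (STDR, R1) per person —
the minimal generative structure consistent with a Cox analysis of
first-presentation events; hazards are constant, so cohort entry (which
conditions on remaining event-free through the baseline pair) does not
distort post-baseline hazards (memorylessness).

Presentation details without a published anchor, fixed once: a non-PDR STDR
presentation is R2 or M1 with equal probability; the diseased grade is
placed in one randomly chosen eye; continuous age is uniform within its
band; diabetes duration is normal(4.0, 5.3) truncated at zero — note the
*realised* mean/SD after truncation are ≈6.1/4.0 years; a small fraction
(0.5%) of persons has ethnicity unrecorded so the complete-demographics
cascade step is exercised. Staggered uniform entry over the ten-year window
plus the 8-year cap yields a realised mean post-baseline follow-up of
≈3.4 (SD 2.2) years.

The visit-gap log-normal cannot match a median of 1.0 *and* both quartiles
0.9/1.1 with two parameters; the median and the IQR width are matched
exactly (σ = asinh((q3−q1)/2m)/z₀.₇₅), placing quartiles at 0.905/1.105.

What the generator does **not** model: mortality and de-registration,
migration, HbA1c or treatment effects, grade regression, eye-level
discordance dynamics, behavioural response to interval changes, or
covariate-dependent attendance. Passing tests therefore demonstrate that the
estimators recover known truth under the assumed structure — not that real
registries satisfy that structure.

## Estimation

Person-time is summed follow-up within stratum; rates default to exact
Poisson (Garwood) intervals, with normal and log-normal Wald alternatives —
the published intervals for this design are not exactly reproducible by any
single textbook method, so the method is configuration, never hard-coded,
and is recorded in every estimate. Kaplan–Meier curves and yearly cumulative
incidence use the product-limit estimator (lifelines). The Cox model uses
Efron's tie correction (annual visit data are heavily tied) and reports Wald
intervals; categorical age is the primary parameterisation, with continuous
age per 5 years as a variant — both cannot sit in one identifiable model.
Levels with no members are reported as NaN rows rather than silently
dropped; levels with members but no events keep their (effectively
unbounded) Wald intervals. Proportionality is checked numerically: Pearson
correlation of each term's scaled Schoenfeld residuals with event time,
flagged "undefined" when residuals are degenerate (fewer than three events
or zero variance).

## Policy simulation

Cycle assignment is time-based: cycle c covers elapsed time in
((c−1)·14, c·14] months from baseline, boundary inclusive; an ordinal
(visit-counting) assignment is available for sensitivity analysis. Under the
biennial parity only even cycles are attended; an event detected in an odd
cycle is delayed by one year (the reported convention), and the next even
cycle's attended visit, when one exists, is recorded as the would-be
detection date. Events whose person never attends again still count as
delayed — the delay is a property of the schedule, not of subsequent
attendance. Delay burden is delayed events per 100,000 eligible persons with
Clopper–Pearson intervals ("standardised" rates in this design are
arithmetically crude per-100,000 proportions, which is what is implemented).
Under perfect annual attendance, constant hazard and an even number of
cycles the delayed fraction converges to one half; empirical fractions above
one half arise from attendance decay and event-timing structure.

## Problem sizes and numerical choices

Parameter-recovery checks and the acceptance script use 20 replicates of
50,000 persons — large enough that the Monte-Carlo standard error of the
mean overall rate is ≈0.004 per 100 person-years while a full run stays
around a minute on one CPU. Fixed seeds drive `numpy.random.default_rng`
exclusively; a fixed seed reproduces registries byte-for-byte in CSV form.
Cox convergence follows lifelines' Newton defaults (relative precision
~1e-3 on coefficients). Degenerate inputs: zero hazards give infinite latent
times (no events ever); empty registries produce empty cohorts and a
zero-count cascade; zero-event rate estimates use the closed-form upper
bound −ln(α/2)/T.

## Known limitations

The R1 hazard and the R2:M1 split are unpublished placeholders; delayed-event
*counts* per 100,000 from the simulator should therefore not be read as
programme estimates, though rate ratios between strata are driven by the
configured hazard ratios. Permanent R1 censoring means estimated rates are
first-presentation rates from the clean state. The policy simulation reuses
observed annual attendance, which is optimistic about adherence under a
two-year interval.
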