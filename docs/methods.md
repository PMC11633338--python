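# Methods

## The measurement model

A monitored day is modelled as 1440 one-minute epochs of acceleration
magnitude (gravity units per minute, g·min) from a wrist-worn device,
midnight to midnight.  Each epoch belongs to exactly one of five
states: sleep, sedentary, light physical activity (LPA),
moderate-to-vigorous physical activity (MVPA), or monitor non-wear.
The five daily totals always sum to 1440 — conservation is an invariant
of every processing step, not a rounding convention.

**Intensity classification.** Waking worn epochs are classified by the
magnitude cutpoints 118 / 403 / 1131 g·min (sedentary < 118 ≤ LPA
< 403 ≤ moderate < 1131 ≤ vigorous; MVPA pools the top two).  Cutpoints
are inclusive on the left, so the class index equals the number of
cutpoints at or below the magnitude — a convention chosen because it
makes the classifier a monotone step function with an elementary
counting oracle.

**Sleep.** Sleep is *sleep period time* (SPT): minutes from detected
onset to offset.  Onset is the start of the first run of ≥ 10
consecutive quiescent epochs (< 40 g·min) within ± 60 min of the diary
bedtime; offset is found symmetrically from the diary wake time.
Without a diary the fallback is the longest quiescent block, accepted
at ≥ 200 min.  Sleep efficiency is the percentage of SPT spent
quiescent and is carried alongside (not subtracted from) the sleep
domain: the four behaviour parts close to 1440 only under the SPT
reading.  Habitual sleep straddles midnight, while each monitored day
is a self-contained 1440-epoch series; days are therefore treated as
*circular* for sleep detection.  The synthetic generator emits
per-day stationary profiles, for which the circular treatment is exact;
on real multi-night recordings it is an approximation that assigns each
night to the day containing its onset-anchored window.

**Non-wear.** Runs of ≥ 60 consecutive epochs below 10 g·min whose
range stays under 5 g·min — the flat signature of an unworn device.
Within a long low run the range criterion is applied to maximal stable
segments (greedy split) rather than all-or-nothing, so a borderline
flanking epoch cannot erase a genuine block.  Non-wear during the sleep
period counts as sleep; the non-wear total covers waking hours only.
The exact non-wear rule of wrist protocols is rarely published; all
parameters (floor, range, minimum run) are exposed in `AccelConfig`.

**Validity and weighting.** A day is valid with ≥ 600 min of waking
wear and ≥ 200 min of sleep (inclusive thresholds); a participant is
included with ≥ 4 valid days of which ≥ 1 falls on a Saturday or
Sunday.  Weighted daily minutes are (5·weekday mean + 2·weekend
mean)/7.  If all of a participant's valid days are weekend days the
weekend mean is used alone rather than failing; the inclusion rule
makes the converse case (no weekend day) an error by construction.

## Compositional analysis

The four behaviours form a composition on the simplex closed to
1440 min.  Non-wear is redistributed proportionally over the behaviours
(scale by 1440/(1440 − non-wear)) before analysis, the standard
treatment when missingness is assumed unrelated to behaviour.  The
compositional mean is the per-part geometric mean, re-closed.

**ilr coordinates.** The sequential binary partition is the pivot
scheme: coordinate *i* contrasts part *i* against the geometric mean of
the later parts, with orthonormal contrast matrix V (so the map is an
isometry between Aitchison and Euclidean geometry — verified
numerically to 1e-8 in the tests).  Four cyclic rotations of the part
order put each behaviour in the leading position; cyclic ordering of
the trailing parts is the convention of the pivot-coordinate
literature, and the choice is immaterial to the model space (all
rotations are orthogonal re-expressions — fitted values, R², distances
and reallocation predictions are rotation-invariant).  All logarithms
are natural; coefficients are per unit of natural-log ratio.

**Zero replacement.** Some participants record no MVPA at all, and
log-ratios do not admit zeros.  Zeros in MVPA are imputed below a
detection limit (default: the smallest observed positive MVPA) by the
conditional expectation of a left-censored lognormal fitted by EM on
the log scale; because the truncated-normal conditional mean lies below
the truncation point the imputed value is below the detection limit by
construction.  A simple multiplicative replacement (δ = 0.65 × limit)
is available as a config fallback and serves as the independent oracle
in tests.  The non-zero parts of an amended composition are scaled down
multiplicatively to preserve the 1440 total.  Replacement is applied at
the participant level (after the 5:2 weighting): weighting first keeps
the daily summaries free of imputed values, and a single imputation per
participant is better determined than one per zero-MVPA day.

## Outcome models and isotemporal substitution

Outcomes (PCS-12 / MCS-12 quality-of-life scores) are fitted by OLS on
the three ilr coordinates, optionally plus covariates, one model per
rotation; each rotation's leading coefficient is the interpretable
"this behaviour versus the remaining" effect.  Both unadjusted and
covariate-adjusted modes exist because small feasibility samples rarely
support the full covariate set.

One-for-remaining reallocation moves Δ minutes into a focal behaviour
while the remaining behaviours shrink proportionally to their share of
the remainder.  The predicted outcome difference is the linear contrast
(ilr(new) − ilr(ref))ᵀ·β̂ — covariates cancel because they are held
fixed (at sample means; the reference composition is the compositional
mean) — with a 95% band from aᵀVa and the t-quantile at the residual
degrees of freedom.  Grid points that would drive a part non-positive
are flagged infeasible, never extrapolated.  The default grid is ± 60
min in 5-min steps.

## Feasibility and power

Feasibility metrics are ratios of recruitment-flow counts, reported to
one decimal; Likert burden/value items are summarised as median (IQR)
with inclusive (Tukey) quartiles.  Required sample size solves for the
smallest n whose overall regression F test (numerator df = number of
predictors u excluding the intercept, denominator df = n − u − 1,
noncentrality λ = f²·n) reaches the requested power, evaluated from the
noncentral-F distribution directly; recruitment numbers inflate by
⌈n/(1 − dropout)⌉.  With this df convention the alternative
λ = f²·(u+v+1) parameterisation is algebraically identical; the flag
exists for designs whose denominator df is reduced by untested terms.
The numerator-df convention (predictors excluding intercept) is taken
as the default reading of "8 predictors"; callers can pass any u.

## The synthetic cohort

The generator's defaults are the study conditions: 29 participants ×
14 days; daily means 484.6 (sleep) / 747.1 (sedentary) / 172.4 (LPA) /
17.5 (MVPA) min plus 18.4 min non-wear (exactly 1440); age 68.4 (SD
9.2) years, 92% male; PCS-12 35.5 (SD 6.9) and MCS-12 49.1 (SD 12.2);
75% sleep efficiency; 15% of participants with zero MVPA (exercising
zero replacement); 14% who never wear the monitor (exercising the
retention metric, 25/29 = 86.2%).

Between-person spreads are not published for this population; the
defaults (SD 55 / 45 min for sleep / LPA, sedentary absorbing the
remainder, MVPA lognormal with σ = 0.77 so that its median sits near
0.74 × mean, matching the reported right skew) are chosen once as
plausible for older adults with restricted mobility and are free
parameters, not estimates.  Day-to-day wobble defaults to SD 20 min;
weekend days get a 1.05 multiplier on sedentary time so the 5:2
weighting is consequential; diary misreport noise is Gaussian with SD
10 min truncated at ± 3 SD (diaries are imprecise, not wrong by hours).

Epoch magnitudes are drawn uniformly *within* each intensity class's
cutpoint interval, which makes classification exactly invertible; a
guard band of upper-range sedentary epochs (41–117 g·min) flanks the
sleep window so onset/offset detection cannot drift into waking time,
and planted non-wear blocks (60–120 min, occurring with the probability
that matches the expected daily non-wear) sit away from the window
edges.  Under these conditions the zero-noise pipeline reproduces the
planted daily minutes exactly, which is what the round-trip tests
assert.  Outcomes are drawn from a linear model on the rotation-0 ilr
coordinates of the true composition (zero-MVPA participants use a 2-min
latent MVPA floor for the outcome model only), with intercepts
calibrated so the expected outcome at the target composition equals the
published mean.

What the generator does **not** emulate: circadian structure within
waking hours, activity bouts (epochs are shuffled), postural
transitions, device noise or calibration drift, naps or fragmented
nights, and weekday-specific routines.  Passing round-trip tests
therefore demonstrate the correctness of the processing rules under
their own definitions, not the field validity of the cutpoints or
sleep algorithm on real recordings.

## Problem sizes and numerics

The test suite and acceptance script use the study-sized cohort (29 ×
14 days ≈ 585k epochs, a few seconds to generate and process), 1000
random compositions for the ilr property checks (tolerance 1e-8), and
100 replicate cohorts of n = 200 participants (generated at the
participant level, without epoch series) for coefficient-recovery
checks.  EM zero replacement iterates to 1e-10 on the log scale, capped
at 200 iterations.  Rank deficiency in regression designs is detected
before fitting and reported with the offending columns.  Reallocation
grids mark infeasible deltas rather than clipping them.

## Known limitations

The published recruited-sample figures for a future definitive study
are not reproducible under any standard noncentral-F convention we
examined (the f² = 0.2 case in particular implies a much larger sample
under every standard reading); the package reports its own computed
sample sizes alongside the dropout-inflation arithmetic, which does
reproduce.  The sleep detector is a deterministic epoch-level
surrogate for what is, in practice, a semi-manual workflow combining
diaries, visual trace inspection and raw-signal algorithms; its
parameters are exposed in config precisely because they are decisions,
not published constants.  Only 4-part compositions are exercised by the
test surface, although the coda module is written for general D.
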