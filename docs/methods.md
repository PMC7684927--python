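# Methods

`akiflow` re-implements, as a tested pipeline over long-format ICU
chart-event tables, the computational core of a before/after ICU quality
study: event-driven AKIN acute-kidney-injury staging, MDRD-based baseline
creatinine resolution, an eGFR-based enoxaparin dose-compliance audit,
encounter- and cohort-level outcome metrics with a discrete Kaplan–Meier
time-to-AKI curve, and two-cohort comparison statistics. Because the
underlying clinical data are not publicly deposited, a synthetic cohort
generator with known latent AKI trajectories stands in for them; every
cohort-level number the analysis scripts print therefore describes
synthetic data, while the staging, audit and statistics engines are
accepted against independent oracles and published worked examples.

## AKIN staging

Two stage streams are maintained per encounter and combined as the
maximum of their most recent values.

**Urine output (AKI-UO).** Charted urine volumes are cumulative since the
previous charting; the cumulative volume is therefore piecewise linear in
time and is resampled to an hourly grid by differencing at hour
boundaries (equivalently, each volume is spread uniformly over its
charting interval). Each hour is normalised by the most recent weight as
of the hour start (a weight on the boundary applies to the hour that
starts there). Hours not fully covered by charting, or preceding the
first weight, are *missing*: they invalidate every window containing them
rather than counting as zero, since fabricated zeros would manufacture
anuria out of non-charting. At each hour end, trailing windows are
tested:

| stage | rule (defaults) |
|---|---|
| 1 | mean rate over trailing 6 h < 0.5 mL/kg/h |
| 2 | mean rate over trailing 12 h < 0.5 mL/kg/h |
| 3 | mean rate over trailing 24 h < 0.3 mL/kg/h, or all of the trailing 12 h anuric (< 1 mL/h raw) |

The emitted stage is the maximum satisfied among eligible windows; a
point is recorded at the first evaluable hour and at every change. Window
qualification uses the **window mean** by default; the stricter
every-hour-below-threshold reading is available as
`StagingRules(uo_window_mode="all_hours")`, because published electronic
implementations differ and neither reading is canonical. The anuric-hour
threshold is < 1 mL/h rather than exactly zero to tolerate charting
noise. Window means are computed per window (not via a running cumulative
sum) so exact threshold boundaries are not blurred by accumulated
round-off. Intervals are half-open `[start, end)` throughout.

**Creatinine (AKI-Cr).** One evaluation per measurement against the
resolved baseline `b`: stage 3 if `scr/b > 3` or (`scr >= 4.0` mg/dL with
an acute rise `>= 0.5`); stage 2 if `scr/b > 2`; stage 1 if
`scr/b >= 1.5` or `scr − b >= 0.3` mg/dL. Boundary conventions follow the
printed AKIN bands ("1.5–2", "> 2–3", "> 3"). Stages are **not
ratcheted**: the stream is a current state and falls when creatinine
falls.

**Combined.** Evaluated at every instant either component updates;
components with no value yet contribute 0. Renal-replacement encounters
are excluded from analysis cohorts rather than pinned to stage 3, since
RRT confounds both inputs; for bedside-style display the
`annotate_rrt_stage3` overlay pins the series to 3 inside RRT intervals
without touching the analysis path.

## Baseline creatinine

When no baseline is charted, it is back-calculated by inverting the
re-expressed 4-variable MDRD equation

    eGFR = 175 · SCr^(−1.154) · age^(−0.203) · 0.742[female] · 1.212[black]

at an assumed-normal eGFR of 75 mL/min/1.73 m² — the established
back-calculation convention. Coefficient set (175 vs the older 186), the
assumed eGFR, and the race coefficient are all configurable
(`MDRDParams`), because validated deployments differ in their constant
set. The inversion is algebraic and exact (round-trip identity holds to
10⁻⁹ relative).

## Exclusion cascade

Applied in fixed order with first-match counting, so counts conserve the
input size: stay ≤ 24 h (strict), missing demographics, age > 90,
admission oligoanuria, RRT during stay, insufficient data. "Admission
oligoanuria" is operationalised as a mean weight-normalised output below
0.5 mL/kg/h over the first 6 h with full charting coverage of that
window; encounters without that coverage are not flagged under it. This
numeric reading is a declared choice — the source criterion is named but
never quantified. "Insufficient data" means no route to any stage value:
neither (urine + weight) nor any creatinine.

## Enoxaparin audit

Every administered (nonzero) dose is judged against the recommended daily
dose for the closest preceding eGFR; correct means not exceeding it.
The default table — `[0, 20) → 0 mg`, `[20, 30) → 20 mg`,
`[30, ∞) → 40 mg` — is reconstructed from the two published anchors (20 mg
in the 20–30 band, contraindicated below 20) plus the standard 40 mg
prophylactic dose, with half-open bands; the full table is configurable.
Doses before any eGFR are removed from the audit, not judged. The audit
carries its own whole-encounter filters (dialysis at any time, maximum
charted weight > 100 kg), independent of the staging cohort's cascade.
Per-administration judgement is the default; `mode="daily"` sums
administrations over each 24 h day of stay and judges the total against
the daily ceiling — the right reading when twice-daily dosing is in play
— but stays non-default because dosing intent per administration is what
the chart records.

## Outcomes

* **Admission stage**: the first combined evaluation within 6 h of
  admission; later first evaluations leave it unknown, which is tallied
  separately and counted as not-admitted-with-AKI in cohort tables.
* **Discharge stage**: the combined value at the last urine or creatinine
  measurement.
* **Daily maxima** (days 1–5): maximum of the combined step function over
  each half-open 24 h window, with last-value carry-forward (the stage is
  a state persisting between evaluations); an evaluation exactly on the
  window start overrides the carried value. Days starting at or after
  discharge are absent.
* **Progression flags**: any consecutive move from value 1 to > 1 (1→3
  counts) and from 2 to 3; latched once per encounter.
* **First AKI day**: day of the first nonzero combined evaluation under
  the half-open day convention (floor of elapsed hours/24, plus 1).
* **Kaplan–Meier**: a discrete daily product-limit estimate of remaining
  AKI-free over days 1–10; encounters discharged without AKI are censored
  and still count at risk on their discharge day; admission-AKI
  encounters are day-1 events by default (config-excludable, since the
  source convention is unstated). Cross-checked against an established
  survival package on tied daily data.
* **Cohort table**: max-stage distribution and any-AKI prevalence are
  reported over encounters *not* admitted with AKI — the denominator
  that reproduces the published control-arm percentages — and every
  proportion is emitted with its numerator and denominator because the
  published intervention arm is ambiguous in that respect.

## Statistics

The "binomial proportions test" is the pooled two-sample z-test (this is
the reading that reproduces the published p-values 0.00021, 0.0066,
0.0073 from the printed counts); a chi-square-with-continuity variant is
config-exposed. The z p-value tracks an exact binomial mid-p enumeration
to within 0.02 in the approximation's validity regime (pooled np and
n(1−p) ≥ 5 per arm, tail p < 0.15); outside that regime no normal
approximation achieves such agreement and none is claimed. Demographic
comparisons use Student's t from summary statistics (pooled by default,
Welch by flag). Study sizing uses Monte-Carlo power of the one-tailed
Fisher exact test, vectorised through the hypergeometric conditional law
and bit-reproducible under a seed. Reproduction of the source study's
"power 0.86" is **not** claimed: the design behind it (denominator
population, rate mapping of the "15% reduction") is under-specified, so
the operation takes explicit rates and sizes instead.

## Synthetic cohort generator

Latent stages evolve on a daily clock: an optional onset to stage 1
(probability `p_onset`, day drawn from a unit-shaped hazard —
cardiac-ICU onsets concentrate on the first postoperative day,
general-ICU onsets decay slowly across the stay), a Bernoulli progression
to stage 2 the next day (`p_progress_from_1`), an optional 2→3 step
(`p_2_to_3`), then one-stage-per-day recovery. Stage 3 is absorbing until
discharge: a recovery day immediately after a fully oliguric day would
otherwise trip the trailing-24 h window early the next day, and a
same-day resolution of established stage-3 AKI is clinically implausible
anyway.

Emissions are hourly and, in noise-free mode (the default), sit exactly
inside the AKIN band of the latent stage: a stage-1 day charts
0.4 mL/kg/h for its first 8 h (only the 6 h window triggers), a stage-2
day for 14 h (the 12 h window triggers, the 24 h one does not), a stage-3
day 0.25 mL/kg/h throughout; creatinine is charted at each day start at
1.6×/2.5×/3.5× baseline with a matching MDRD eGFR. Admission-AKI
encounters present through creatinine with normal urine output on the
admission day (community-acquired AKI), so they survive the
admission-oligoanuria exclusion. Uncharted latent baselines equal the
MDRD back-calculated value for the encounter's demographics, so staging
is exact in both the charted and estimated branches. Optional truncated
log-normal jitter on both emissions is off by default.

Enoxaparin: one dosing opportunity per day at hour 10. Where the
recommendation is positive, exactly one dose is charted, incorrect with
probability `p_dose_error` (40 mg instead of 20, or 80 mg instead of 40 —
a missed renal adjustment or a therapeutic-dose confusion); the measured
incorrect fraction is therefore exactly Binomial(`p_dose_error`) and the
configured rate is recoverable within its exact binomial confidence
interval. Contraindicated opportunities chart nothing by default;
`p_contraindicated_dose` can inject the published eGFR < 20 error
scenario, at the cost of inflating the measured rate above
`p_dose_error` (the correct counterpart, charting nothing, is invisible
to the audit).

Defaults are the control-phase study conditions: age 63.6 (14.5) y,
32.1 % female, 1.3 % black, 41.8 % general ICU, LOS log-normal with mean
5.8 and SD 6.7 days (floored at 26 h — every encounter exceeds the 24 h
inclusion bar — and capped at 40 days), weight 81 (20) kg, admission AKI
6.5 %, in-ICU onset 33.9 %, stage-1 progression 0.42, 2→3 progression
0.213, dose error 1.72 %, charted baseline 1.6 %, RRT 6.5 %, missing
demographics 0.5 %. `intervention_config()` swaps in the after-phase
rates (progression 0.335, 2→3 0.118, onset 29 %, dose error 0.6 %,
charted baseline 58 %, RRT 7.9 %).

**What the generator does not emulate** — and hence what passing
round-trip tests do not show about real data: irregular charting
cadence and missing-not-at-random documentation, creatinine kinetics
(values jump between bands at day boundaries instead of drifting),
multi-episode AKI, fluid-balance effects, error clustering by clinician
or shift, and the concentration of real dosing errors in the 20–30
eGFR band (synthetic errors are uniform per dose by design, to keep the
configured rate exactly recoverable).

## Numerical and procedural choices

* Timestamps are timezone-naive on a single monotone clock (the source
  data were time-shifted anonymised exports); generator timestamps are
  floored to whole minutes, the charting resolution.
* Creatinine is canonically mg/dL; µmol/L inputs are converted at
  88.42 µmol/L per mg/dL once at read time.
* Degenerate inputs are contracts, not crashes: no weight → urine staging
  uncomputable (flagged), empty series → empty combined series, zero
  eligible doses → absent (None) fractions, empty cohorts → zero counts
  with absent proportions.
* Child seeds for two-phase studies derive from one master seed via
  `SeedSequence.spawn`, keeping phases independent and the whole study
  reproducible from a single integer.

## Problem sizes in the shipped tests and scripts

The analysis drivers default to 800 encounters per phase; the test suite
accepts the staging engine against 500 random 72 h grids, recovers
progression probabilities on 1000 stage-1 encounters and dose-error
rates on ≈20 000 doses, and calibrates the null two-phase comparison
over 200 replicate study pairs of 120 encounters per arm — sizes at
which the binomial confidence intervals under test are a few percentage
points wide, which is what the recovery claims require.

## Known limitations

* The oligoanuria exclusion threshold, the MDRD constant set, and the
  UO window semantics of the originally deployed algorithm are not
  recoverable from the published description; all three are configuration
  with declared defaults rather than asserted truth.
* The per-day outcome granularity hides sub-day episodes shorter than
  the emission profiles used by the generator.
* The pooled z-test is a large-sample approximation; for very small
  strata use the Fisher machinery in `akiflow.stats` directly.
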