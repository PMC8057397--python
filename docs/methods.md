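# Methods

This note records the models, conventions, and design choices behind each
module, and what the synthetic-data experiments do and do not demonstrate.

## Time-series conventions

All channels share one container (`BioSeries`): strictly increasing
timezone-naive local wall-clock timestamps, finite values, a nominal
sampling interval, and a fixed channel (heart rate [bpm], steps
[counts/interval], glucose [mg/dL]). Missing data is an absent sample,
never a sentinel. On read, timestamps are converted to one configured
timezone (standard tz-database behavior; no extra DST heuristics) and
duplicate timestamps are collapsed to their mean — deterministic and
order-independent.

Resampling bins are half-open `[t, t + interval)` labelled by their left
edge, floor-aligned to the interval; every windowed operation downstream
uses half-open `(t − w, t]` lookback windows. Stated once, enforced
everywhere. One channel-specific rule: for steps, an empty bin inside the
observed wear span means "no steps" and becomes 0, because an idle step
counter emits nothing; for heart rate and glucose an empty bin is a missing
measurement and stays absent.

Plausibility bounds (inclusive, configurable) reflect physiological/sensor
limits: heart rate 25–250 bpm, steps 0–300 per minute, glucose
20–600 mg/dL.

## Missingness and outliers

Presence is counted per nominal grid slot, not per raw sample, so
oversampling can never exceed 100%. Per-day fractions always divide by the
full 24-hour day — including partial first/last days — so day-by-hour heat
grids are comparable across days; this is a documented convention, not the
only defensible one. The outlier screen combines the bounds rule with a
spike rule, |value − rolling median(15 min)| > 5 × robust SD, where robust
SD = 1.4826 × MAD; the multiplier is deliberately conservative and
configurable. Series spanning less than one window fall back to the bounds
rule with a warning.

## Resting heart rate

The estimator searches step thresholds n ∈ {0..10, 15, 20, …, 50} and
window lengths m ∈ {5, 10, …, 60} minutes (204 candidates — sedentary
thresholds by hour-scale rest windows without combinatorial blowup) over
heart rate and steps aligned to a shared 1-minute grid. The penalty

    P(n, m) = SD(subset) + λ · SD(all HR) · max(0, f·N − |subset|)/(f·N)

uses λ = 1, minimum subset fraction f = 0.10, and sample SDs (n − 1
denominator; 0 for singleton sets). Subsets that are empty or touch fewer
than `min_days` distinct calendar days (3 when the recording spans ≥ 3
days, else the span) are disqualified with an infinite penalty. Minimizing
subset SD alone would collapse to near-empty subsets; the shortfall term
makes the optimum a low-variation subset that still represents the data.
The rolling step sum is trailing, `(t − m, t]`; a centered window would be
an equally coherent convention but trailing matches the lookback rule used
package-wide. Ties are broken toward smaller m, then smaller n — the
stricter rest definition — and the median of an even-sized subset is the
mean of its two central values. The penalty's functional form is isolated
in one operation so alternatives can be swapped.

A known limitation, visible in the simulations: when step activity recurs
frequently throughout waking hours, the lowest-SD low-activity subset is
the sleep cluster, and the estimate tracks *sleeping* heart rate — several
bpm below wakeful rest. Under the workout-style activity schedule used by
the recovery experiments (steps concentrated in a few exercise bouts), the
optimal subset mixes sleep and quiet wakefulness and the median recovers
the wakeful resting rate to within ~1.3 bpm. Wearable-derived RHR
generally sits near sleeping HR for highly active subjects; interpret
accordingly.

## Sleep detection

Epochs are 5 minutes; an epoch's mean HR is kept only when ≥ 50% of its
expected HR minutes are present. Seed labels are deliberately
high-precision, low-recall: likely-sleep epochs lie inside maximal runs of
≥ 120 minutes in which every epoch has zero steps and mean HR below the
subject's 40th HR percentile; likely-wake epochs have ≥ 50 steps. The
thresholds are configurable; the classifier exists precisely to generalize
from these conservative seeds to the unlabeled middle ground.

Features per epoch: mean HR z-scored against the subject's overall HR
(defined as 0 when the overall SD is 0), rolling mean/SD of epoch HR and
rolling step sum over a centered ±30-minute window, and sin/cos encodings
of 24-hour clock phase. The candidate models are a standardized logistic
regression and an RBF-kernel SVM whose decision scores are Platt-calibrated
on training folds; selection is by stratified 5-fold cross-validated
balanced accuracy (class imbalance is guaranteed), seeded for determinism,
with ties preferring the logistic model (simpler, calibrated
probabilities). The clock-phase pair is *not* standardized: it is already
unit-bounded, and per-coordinate scaling would break the rotational
symmetry that makes detection equivariant under time shifts — shifting both
input series by a whole number of epochs shifts the detected episodes
exactly, which is the formal statement of "no clock prior".

Per-epoch labels (probability ≥ 0.5) pass through a width-5 median filter;
sleep runs separated by < 30 minutes merge; episodes shorter than 60
minutes are dropped. Episodes are non-overlapping and time-ordered; gaps in
the epoch grid count as wake. For per-night reporting, days run noon to
noon so episodes crossing midnight are not split.

## Glycemic variability

The 28-name catalog and each formula are this package's explicit
definitions, grouped so each formula lives in exactly one operation:

* target range 70–180 mg/dL, boundary-inclusive (clinical consensus
  default, configurable); tir + tor = 100 exactly;
* risk transform f(g) = 1.509·((ln g)^1.084 − 5.381) for g in mg/dL;
  rl = 10f² for f < 0, rh = 10f² for f > 0; LBGI/HBGI are means of rl/rh
  over all samples; ADRR is the mean over days of (max daily rl + max
  daily rh); J-index = 0.001·(mean + SD)²;
* MAGE uses the smoothed-extrema dialect: 9-point moving average,
  plateau-tolerant alternating extrema, excursions = consecutive-extremum
  differences exceeding 1 × overall SD, mean of qualifying amplitudes in
  both directions. MAGE has many published dialects; this one is
  brute-force oracle-tested;
* MODD/CONGA24 pair clock times across a 24-hour lag with ±2.5-minute
  tolerance (half a 5-minute CGM interval); CONGA's horizon is fixed at
  24 h to pair naturally with MODD;
* GMI = 3.31 + 0.02392·mean(g); eA1c = (mean(g) + 46.7)/28.7;
* day boundaries are local calendar midnight; SDs use n − 1 throughout.

Metrics with unmet preconditions (MODD on one day, ADRR on one day, MAGE
on a constant trace, …) are reported absent-with-reason; the report always
enumerates all 28 names. Because SDs use the n − 1 denominator, exactly
duplicating every sample leaves location, range, risk, and A1c metrics
unchanged but perturbs SD-family metrics at O(1/n); with a population
denominator the invariance would be exact, but the sample convention was
kept for consistency. The LOWESS trend is local linear smoothing
(statsmodels) with default span 0.15, evaluated at the input time points;
it reproduces a noiseless line exactly at span 1.0.

## Synthetic data

`simulate_hr_steps` builds minute-grid HR as rhr_true + a single 24-hour
circadian sinusoid − sleep_drop inside sleep windows + hr_rise inside
activity bouts + i.i.d. Gaussian noise; steps are zero outside bouts.
Defaults: rhr_true 60 bpm, circadian amplitude 3 bpm, sleep 23:00–07:00,
sleep_drop 5 bpm, noise SD 3 bpm, 7 days. The circadian trough entrains to
the midpoint of the sleep window, so a shifted schedule shifts the whole
physiology coherently — the realistic regime for adapted shift workers, and
the regime in which shifted-sleep detection is a fair test. The default
activity schedule is free-living: three daily workouts (30 min, 80
steps/min, +40 bpm) at fixed offsets after wake-up plus 3-minute walks (40
steps/min, +8 bpm) every 45 waking minutes. `exercise_only_bouts` gives the
workouts-only variant used by the RHR recovery experiments (see the RHR
limitation above). Safe ranges are documented (e.g. sleep_drop < rhr_true)
rather than silently clamped.

`simulate_cgm` builds 5-minute-grid glucose as baseline 100 mg/dL + three
daily meal kernels (linear rise to 80 mg/dL over 30 min, exponential decay
with 60-min time constant) + Gaussian noise (SD 5), 14 days, and records
noiseless closed-form expectations. `degrade_missing` removes an exact
count of grid slots — uniformly at random or as one contiguous block — and
returns the removed-slot mask, so missingness recovery can be checked for
exact equality.

What the generators do *not* emulate: autocorrelated sensor noise, HR
recovery tails after exercise, glucose–insulin dynamics, movement during
sleep, or device-specific artifacts. Passing the recovery experiments
therefore shows the estimators are correct and well-calibrated under clean
structural assumptions, not that they meet any clinical accuracy bar on
real device data.

## Problem sizes and determinism

The test suite and the acceptance script run everything at the scale the
methods were designed for: 7-day minute-grid subjects (10,080 samples) for
RHR and sleep, 14-day 5-minute traces (4,032 samples) for CGM, 20 seeds for
RHR recovery and 10 seeds per schedule for sleep recovery. Every stochastic
component — simulators, cross-validation folds, classifier internals — is
seeded, and repeat runs are bit-identical.
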