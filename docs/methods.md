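# Methods

This note documents the models implemented in `gaitpal`, the choices made
where the method family leaves room, and what the synthetic-data
generators do and do not emulate.

## Activity counts

Counts are the time integral of detrended, rectified acceleration per
5-s epoch, summed over the three axes, in g·s (1 kcount = 1000 counts).
Choices:

- **Detrending** is per-epoch mean removal per axis (default). This is
  the minimal reading of "detrending" and makes the static gravity
  component drop out exactly; per-epoch linear-trend removal is available
  via `PipelineConfig(detrend="linear")`.
- **Axis combination** is the sum of the three per-axis rectified
  integrals, matching common composite-counts actigraphy practice.
- **Integration** uses the rectangular rule (sum × 1/fs). For sinusoidal
  input with whole cycles per epoch the discrete counts match the
  closed form ∫|A sin| dt = (2/π)·A·T to well under 1% at 60 Hz for gait
  frequencies; a caveat is that when the sampling grid falls exactly on
  the rectification kinks (e.g. a 5 Hz sinusoid sampled at 60 Hz with
  zero phase) the rule under-integrates by ~2%. This is a measure-zero
  alignment without practical consequence.
- Trailing partial epochs are discarded, never padded; padding would
  bias both SDs and counts. Recordings at rates that do not divide the
  epoch evenly are linearly resampled to 60 Hz first.
- Epochs with a count rate strictly below 10⁻³ counts/s are inactivity
  and contribute to no activity-time or counts aggregate.

## Gait template

The template-construction procedure is: estimate the dominant stride
period from the biased normalized autocorrelation of the vector-magnitude
signal (search band 0.4–1.75 strides/s, or ±20% around a supplied step
cadence hint); segment peak-to-peak at that period, keeping segments
within 70–130% of it; resample all cycles to the median cycle length;
align circularly to the first cycle by cross-correlation lag; average
pointwise and remove the mean. A calibration-quality error is raised when
no autocorrelation peak reaches 0.3 (constant or aperiodic input).

On a single-speed recording this extracts strides (the asymmetry between
left and right steps makes the stride the true period). On a pooled
4-speed session the dominant shared periodicity is typically the step,
and the template converges to a step prototype; both discriminate walking
well, and the pooled template is the default because the classifier's
features are calibrated on the same pooled session. Per-speed templates
remain possible by calibrating on single-speed recordings.

## Classifier

SDs and SDcc use the population (n) denominator; the choice is irrelevant
after density calibration but fixed for reproducibility. The per-feature
likelihoods P(SDs|walk) and P(SDcc|walk) are Gaussian kernel density
estimates with Silverman bandwidth (a parametric log-normal alternative is
available), fitted on the treadmill epochs only — the classifier never
sees labeled nonwalking data. Each fitted density is sampled onto a
512-point uniform grid spanning the data range ±5 bandwidths and the
grid-plus-linear-interpolation object *is* the model: evaluation is zero
outside the grid, the grid integrates to 1 within 10⁻³, and JSON
round-trips are bit-exact, so scoring is identical before and after
serialization.

The walk score k·P(SDs|walk)·P(SDcc|walk) with
k = 0.5/(0.14·max joint calibration likelihood) is an unnormalized
score, not a calibrated probability: at the best calibration epoch it
reaches 0.5/0.14 ≈ 3.57, and its complement can be negative. The
implementation therefore never relies on P(nonwalk) ≥ 0 and uses the
algebraically equivalent decision rule: walk iff the joint likelihood
exceeds 0.14 × the calibration maximum. The maximum is taken over the
calibration epochs (not the continuous feature plane). A score of exactly
0.5 goes to nonwalk (conservative toward the majority class;
configurable). The constants 0.5 and 0.14 are empirical and configurable.
Inactive epochs bypass classification entirely.

## Aggregation

Bouts are maximal runs of consecutive walk epochs with no gap tolerance —
one nonwalk or inactive epoch ends a bout. Bouts shorter than 60 s are
short walks, 60 s or longer long walks. Day-level identities hold exactly:
walking = short + long and activity = walking + nonwalking, in both time
and counts.

Wear time, when not supplied externally, is the recorded duration minus
non-wear, with non-wear defined as runs of ≥60 consecutive minutes of
exactly-zero-count epochs (the standard actigraphy convention; the rule
distinguishes a device lying still, which still shows sensor noise, from
a device that is off). Days with wear under 10 h — a strict "less than",
so 10.0 h is valid — or with a timestamp gap over 1 h are excluded.
Subject summaries are unweighted means over valid days (daily activity is
treated as ergodic, so dropping days does not bias the mean).

Intensity is defined per subject as mean daily counts divided by mean
daily time (a ratio of means), and cohort intensity as the mean of the
per-subject intensities — not the ratio of cohort means. Under this
reading the reference cohort's nonwalking row is internally consistent
(3.5 kcounts / 500 min = 7.0 counts/min) while walking rows, being means
of per-subject ratios, need not be. Category intensity is reported as
missing (not 0) when the category time is zero.

## PAL models

PAL = TEE/BMR, both in the same unit (MJ/day or kcal/day); values outside
1.1–2.6 trigger a plausibility warning. Count predictors enter
regressions in counts/day, which puts slopes on the 10⁻⁵ scale of the
reference equations. The standard error of the estimate is the residual
SD with the n−p−1 denominator. Stepwise selection is forward entry at
p < 0.05 with backward removal at p > 0.10 (the classic defaults of
mainstream statistics packages); both thresholds are configurable. Note
the structural consequence: with one uninformative candidate the
entry rule falsely includes it in about 5% of datasets — "selects exactly
the informative predictors" therefore cannot be expected in more than
~95% of replicates even at perfect power, and observed rates hover a
point or two below that once finite power is accounted for.

## Synthetic data

The gait generator is a harmonic series at the step frequency
(fundamental + 2nd and 3rd harmonics), plus a stride-frequency component
(`cycle_asymmetry`) that breaks left/right step symmetry, plus white
Gaussian sensor noise; the vertical axis carries 1 g gravity and the
horizontal axes are attenuated (0.55, 0.35), phase-shifted copies.
Treadmill speed maps affinely to step frequency (1.10 + 0.14·speed Hz)
and amplitude (0.05 + 0.055·speed g); only monotonicity of this map is
relied on. Defaults — 1.8 Hz steps, 0.3 g amplitude — yield walking at
≈21 counts/min, matching the reference cohort's walking intensity.

Nonwalking movement is 0.3–8 Hz band-limited noise rescaled so the mean
epoch count rate equals the requested intensity exactly (counts are
linear in amplitude); its default, 7 counts/min, matches the reference
nonwalking intensity. Idle wear is the same noise far below the
inactivity threshold; non-wear is exact zeros (device off), so the
non-wear detector and the inactivity rule are exercised separately.

The default free-living day carries ~15 h of wear, ~500 min of nonwalking
movement, and ~130 min of walking of which 83% lies in 10–55 s bouts,
with bout speeds drawn across the full treadmill range; walk bouts are
interleaved with non-walk segments so each scheduled bout is one bout in
the ground truth. Segment durations snap to the 5-s epoch grid, so truth
labels align exactly with epochs. Cohorts are generated at the summary
level: per-subject mean daily times and intensities per category are
drawn from (mean, SD) distributions matching the reference table,
day-to-day variation has a 15% coefficient of variation over 14 days, and
true PAL is a configured linear model of the subject's counts plus
Gaussian noise (defaults: the simple reference equation with SD 0.13,
n = 31 — the reference PAL-subgroup size).

**What passing tests show, and what they do not.** The generator's
walking is far more stereotyped than real gait: no orientation drift, no
posture changes, no biomechanical variability beyond the speed map and
sensor noise, and nonwalking movement has no periodic confounders
(biking, stair climbing). Near-perfect epoch accuracy on synthetic days
therefore demonstrates the internal consistency of the
template/likelihood machinery, not field performance; on real recordings
the SDs/SDcc distributions overlap more and accuracy will be lower.

## Problem sizes and determinism

All generators are deterministic given a seed, with independent streams
per subject/day derived from it. The end-to-end suite uses one simulated
treadmill session and 200 simulated days; regression recovery uses 200
cohorts of n = 31. These sizes give Monte-Carlo standard errors well
inside the asserted tolerances. The acceptance script
(`scripts/acceptance.py`) evaluates the deterministic reference-equation
targets; it accepts a seed for interface uniformity.

## Known limitations

- No GT3X binary parsing (CSV exports only), no band-pass pre-filtering,
  no orientation correction or multi-placement fusion.
- Everything non-walk is a single class; no multi-activity recognition.
- The template construction is a standard prototype-averaging procedure;
  laboratory-specific variants may differ in detail.
- Energy-expenditure measurement (isotope kinetics, calorimetry) is out
  of scope: TEE and BMR enter as numbers.
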