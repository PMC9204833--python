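# Methods

This note documents the models, parameter choices and numerical decisions
behind `sitstand`, and what the synthetic-data experiments do and do not
demonstrate.

## Signal model and axis alignment

All signals are accelerations in units of g. At quasi-static postures an
accelerometer reads the gravity reaction, so the per-sample vector norm of
a noiseless static recording is exactly 1 g; this is an invariant of the
generator and a test of the alignment stage (a rotation, hence
norm-preserving to machine precision).

Calibration estimates gravity as the normalised mean of a ≥ 5 s quiet
standing recording; the norm of the mean must lie in [0.8, 1.2] g or the
calibration is rejected (`CalibrationQualityError`). The anatomical triad
is completed by projecting the site's nominal anterior axis (device x for
both sites) out of the gravity direction; (AP, ML, CC) is right-handed
with CC = +1 g in quiet standing. Only CC-derived quantities are invariant
to the sensor's heading about gravity; AP/ML depend on the nominal
mounting assumption, which is why the test suite asserts CC-invariance
under device rotation about gravity but not AP/ML-invariance.

Filtering is 3rd-order Butterworth, applied forward-backward by default so
event indices are not lag-shifted; this squares the magnitude response
(6th-order effective attenuation, −6 dB at the cutoff). A causal mode
exists behind `zero_phase=False`. Filter tests bound measured attenuation
by the analytic single-pass magnitude, which the zero-phase default always
beats.

The dominant frequency (the 30CST repetition rate, used as the
delineation low-pass cutoff) is the largest periodogram peak in
0.1–1.5 Hz; the band must carry ≥ 10% of the non-DC power, otherwise the
series has no meaningful repetition rate and an error is raised. The band
comfortably contains plausible chair-stand rates (5–20 repetitions per
30 s → 0.17–0.67 Hz) and the power-fraction gate rejects pure noise.

## Chair-stand delineation

Stand events are prominence-gated maxima of the filtered thigh CC
(prominence ≥ 0.2 g, separation ≥ 1 s — robust to residual ripple); sit
events are the refined minimum of each inter-stand segment, including the
segments before the first and after the last stand when they dip at least
the prominence below the adjacent stand (a rise truncated by the end of
the test therefore never counts, so the repetition count includes
completed stands only). This construction enforces the alternating
sit/stand grammar directly. On flat (noiseless) plateaus the refined
extremum is the plateau centre.

The mid-transition point is the first crossing of the 50%-amplitude level
between the event's sit and stand extrema, and splits the event into its
two halves; a flat segment falls back to the temporal midpoint with a
flag.

**Boundary events.** The first and last sit phases touch the recording
edge, where two artifacts coincide: the zero-phase filter pads the series,
and the long static plateau passes the low-pass filter unattenuated, so
the event's own 50% level (computed from its unusually deep sit extremum)
is biased. Boundary events therefore take their mid from the trial-median
50% amplitude level, and their sit index is the stand extremum mirrored
through that mid under the ramp-symmetry assumption. Interior events use
the per-event definition exactly. Without this, the two boundary
transitions of every trial are systematically mis-timed at slow repetition
rates — an edge-filtering artifact, not a detection failure.

Durations are extremum-to-extremum. With static holds between movements
this reads the ramp plus half of each adjacent hold, which is the honest
behaviour of an extremum-based measure; duration-accuracy tests therefore
use back-to-back (zero-hold) trials where the extrema are the ramp
vertices.

Detected events are matched to ground truth on mid-transition times,
the landmark invariant under symmetric filtering.

## Free-living detection

Windows are 4 s, non-overlapping; the classifier is a seeded random
forest (200 trees, single-threaded) over 16 per-window summary features
(per sensor: per-axis mean and SD, vector-norm SD, mean absolute
successive difference of the norm). The recurrent architecture these
stages model in the source protocol (LSTM 215 units / BiLSTM 125 units
with 30%/40% dropout, Adam) is kept as descriptor fields on
`ClassifierConfig`; no deep-learning framework is a dependency of this
package, and the pipeline's contract is the bout sequence, not a specific
decision surface. Training-corpus hygiene (participant-disjoint splits) is
enforced structurally by `split_by_participant`.

Candidate windows are 18 s of raw data around each boundary of every
sitting bout > 30 s (strict). The three validation gates are evaluated on
the 0.4 Hz low-pass CC over the whole window, and **all** gates are always
evaluated so every rejection carries its complete reason set
({no_halfg_crossing, insufficient_range, too_long, no_extrema}) — the
audit trail that replaces manual visual inspection.

**Transition localisation and duration.** The transition region is found
by slope thresholding (contiguous samples with ≥ 10% of the anchor-side
peak slope, anchored at the 0.5 g crossing nearest the window centre; an
absolute floor of 0.05 g/s rejects motionless windows). Because the 0.4 Hz
filter broadens any ramp by roughly its ~1.6 s rise time, the raw region
span overestimates short transitions badly. The detector therefore fits
the assumed sigmoidal (smoothstep) ramp — passed through the *same*
filter — to the observed window and places the sit/stand indices at the
fitted ramp endpoints: duration is still the span between the selected
extrema, but corrected for the known instrumental broadening. On ideal
ramps of 1–4 s the recovered duration is within 0.09 s; a 5 s transition
is rejected as too long. For real movements that deviate from a sigmoid
the duration is a model-based estimate; the model is the same kinematic
assumption used throughout the package.

## Feature catalogs

* Supervised 30CST: 9 temporal (avg/median/max/min × {si-st, st-si} +
  repetition count) + 144 acceleration (6 statistics × 3 axes × 2 phases ×
  2 halves × 2 sensors; 72 per sensor) = 153.
* Unsupervised 30CST: 19 temporal summary metrics across assessments +
  the same 144 acceleration metrics pooled across assessments = 163.
  Participants with fewer than four usable assessments are flagged
  ineligible and emit no features.
* Daily life: 10 temporal (min/max/avg/median/CV × 2 phases) + 192
  acceleration (the 6 chair-stand statistics plus CV-of-peak and
  CV-of-min). The printed total of 128 in the source description of the
  daily-life acceleration set is not reproducible from any consistent
  reading of its stated statistics × axes × halves × phases × sensors; the
  full enumeration is implemented and 128 is not asserted anywhere.

Conventions: "peak" is the signed maximum and "minimum" the signed minimum
of the 5–20 Hz band-passed signal (minima are typically negative);
percentiles are linear-interpolation order statistics over the pooled
band-passed samples of a phase-half; CV is the sample standard deviation
(n−1) over the mean. The band-pass guarantees all acceleration features
are invariant to constant offsets of the raw signal. Halves shorter than
3 samples, CVs of single events and zero-repetition trials produce
explicit NaNs with flags, never silent zeros.

## Screening statistics

The normality gate is a Kolmogorov-Smirnov test against a normal with the
sample moments (non-normal iff p < 0.05; constant samples are non-normal
by definition). Groups below 4 observations skip the gate and use the
rank test, whose validity does not rest on normality. The Wilcoxon branch
uses the normal approximation with tie correction and no continuity
correction, so a symmetric tie-free null gives p = 1 exactly. Cohen's d
uses the (n−1)-weighted pooled SD, reported as magnitude plus direction.

The unadjusted AUC is the Mann-Whitney estimator computed from average
ranks, which equals pairwise concordance counting with ties worth one
half (asserted to 1e-12 against a brute-force oracle). Covariate
adjustment uses placement values: the marker is regressed linearly on the
covariate within controls, and the adjusted AUC is the mean exceedance of
case residuals over the control residual distribution. A pooled-sample
residualisation variant is available (`method="residualize"`); both are
reported by the screen, since protocol descriptions of "age-adjusted ROC"
rarely pin down the estimator. A degenerate covariate falls back to the
unadjusted AUC with a flag. No multiple-testing correction is applied in
the default screen-then-rank workflow; Benjamini-Hochberg is available
off by default.

Calibration checks (all recomputed by `scripts/acceptance.py`): type-I
error of the gated test at n = 16/21 over 10,000 null simulations; mean
empirical AUC over 500 simulations against the binormal value Φ(d/√2)
for d ∈ {0.5, 1.0, 1.15}; and the confounding scenario below.

## The synthetic generator

The generator emulates what the analysis assumes, not full biomechanics:

* Thigh CC moves between 0.05 g (sitting) and 0.98 g (standing) along
  smoothstep ramps; AP completes the gravity norm to 1 g. The chest stays
  near 1 g upright with a configurable transient dip during transitions
  (a stand-in: the protocol source gives no chest kinematic model, and
  chest acceleration features should be read accordingly) and ~0 g lying.
* Transients are 7–14 Hz Gaussian-windowed bursts at transition midpoints
  (exercising the band-pass feature path independently of the low-pass
  event path); walking adds a 1.8 Hz gait oscillation; "other" (running,
  stairs, unclassifiable) is upright with large broadband dynamics;
  measurement noise is white Gaussian per axis.
* Device axes are tilted from anatomical axes by a configurable mounting
  misalignment (default 5°), and matching calibration recordings are
  generated, so alignment is genuinely exercised.
* Chair-stand defaults — 10 repetitions, 1.2 s ramps, 0.25 s holds, 3 s
  seated lead-in/tail, 0.02 g noise, 0.05 g bursts — were fixed once to
  resemble a mildly impaired cohort (~10–13 repetitions, 1.2–1.5 s
  transitions). Free-living schedules alternate stand/sit/walk cycles
  with sitting bouts of 40–900 s, occasional "other" segments, and
  sit-flanked nightly lying; all sitting bouts clear the 30 s gate by
  construction, so the detector's sensitivity denominator is exact.
* Cohorts draw unit-variance Gaussian features with configured Cohen's d
  group shifts and group-specific age distributions (controls 44.7 ± 12.4,
  cases 55.2 ± 10.3 years). The confounding scenario generates a feature
  driven by age alone (slope 0.7 on standardised age, unit total
  variance): with age-shifted groups its unadjusted AUC is ≈ 0.68 while
  any correct covariate adjustment returns it to ≈ 0.5.

What passing tests show: the pipeline recovers transitions whose
kinematics match its assumptions, its gates reject the artifact classes
the generator produces, and its statistics are calibrated. What they do
not show: performance on real sensors (soft-tissue artifact, sensor
detachment, non-sigmoidal or multi-phase transitions, wheelchair or
vehicle sitting), or the clinical discriminative validity of any feature.

## Problem sizes and scenario choices

Simulated experiments are sized to be decisive yet quick: the delineation
grid uses 5-repetition trials over durations {0.8, 1.2, 2.0, 3.0} s ×
noise {0, 0.02, 0.05} g (120 transitions); the detector acceptance runs a
full 48 h free-living stream (~300 transitions) in the acceptance script
and 3 h in the test suite; statistical calibration uses 10,000 null
simulations. The end-to-end ranking check (one d = 1.15 feature among 150
nulls) is run at n = 50 per group: a power analysis shows that at the
clinical scale of n = 16/21 the null-AUC sampling SD (~0.10) makes it
likely that some gated null out-ranks the true feature, so "the true
feature ranks first" is only a fair expectation of the machinery at
moderate cohort sizes.

## Known limitations

* The chest transition kinematics are a configurable stand-in.
* Daily-life durations are matched-model estimates (see above).
* The activity classifier is a feature-based model standing behind the
  published recurrent architecture's contract; no attempt is made to
  reproduce specific clinical-corpus accuracies.
* AP/ML features depend on the nominal mounting orientation; only CC
  quantities are heading-invariant.
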