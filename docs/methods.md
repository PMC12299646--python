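# Methods

## The task model

The pipeline analyses a seated drinking task: after a ≥ 5 s rest, the
participant reaches for a bottle, transports it to the mouth, drinks,
transports it back, and returns the hand to rest. Five phases are
delimited by six events; four are kinematic (elbow-extension maxima,
shoulder-elevation initiation and peak) and two are accelerometric (hand
acceleration leaving/re-entering a ±0.3 m/s² band around its rest mean).
Kinematics are sampled at 100 Hz, hand acceleration and surface EMG of six
scapular muscles at 2000 Hz.

All phase windows are inclusive of both boundary samples, so an extremum
that defines a boundary belongs to both adjacent phases. Between-system
synchronisation is assumed perfect (both blocks share the recording
clock); clock drift between devices is out of scope.

## Processing chain and its constants

| step | design | default | why |
|---|---|---|---|
| EMG band-pass | Butterworth, order 2, zero-phase | 20–450 Hz | surface-EMG signal band |
| EMG envelope | sliding RMS, centre-aligned, reflect-padded | 100 samples (50 ms at 2000 Hz) | amplitude envelope on the raw time base |
| EMG normalisation | mean envelope of the central 3 s of each of three 5-s submaximal repetitions, averaged | — | ramp-up/-down excluded; %SVIC scale |
| EMG down-sampling | non-overlapping block means to the kinematic rate | 20:1 | per-phase EMG means use the same windows as kinematics |
| acceleration low-pass | Butterworth, order 4, zero-phase | 4 Hz | movement-band acceleration for event detection and velocity |
| angle smoothing | Butterworth, order 2, zero-phase | 6 Hz | self-paced reaching lives below ~2 Hz; tames the extreme-value noise bias of max/min metrics |
| event smoothing | Butterworth, order 2, zero-phase | 2 Hz | extremum/velocity-threshold localisation under sensor noise |
| rest window | first 5 s of the recording | 5 s | static reference posture |

Every filter is applied forward–backward (`filtfilt`), which preserves
event timing at the cost of doubling the effective order and of smearing
onsets symmetrically: a detected onset can precede the physical movement
start by a few milliseconds. The acceleration rest mean excludes the last
0.5 s of the rest segment so this smear cannot contaminate it.

Sustain rules make the threshold detectors robust to single-sample noise
crossings: 50 ms outside the band for the onset, 200 ms inside it for the
end, 100 ms above 5°/s for shoulder-elevation initiation. The thresholds
are part of the event definitions; the sustain windows and the 5°/s
initiation criterion are package operationalisations, all configurable
(`SegmentationParams`).

## Metrics

ROM is max − min inside the phase window; the scapulohumeral rhythm is
the ratio of shoulder-elevation to scapular upward-rotation ROM over the
drink phase (denominator floor 0.5° guards degeneracy). Trunk
compensation is the signed deviation of largest magnitude from the rest
posture. % time-to-peak acceleration locates the largest |acceleration|
in the reaching phase on the whole-task clock (earliest-sample
tie-break).

Movement smoothness is the log dimensionless jerk of the hand velocity
over onset→end. Velocity comes from trapezoidal integration of the
filtered acceleration with a linear drift correction pinning the final
velocity to zero (the hand rests at both task ends). The jerk cost is
C = ½∫j² dt with j the third derivative of position — the conventional ½
makes C = 360·A²/D⁵ for a minimum-jerk segment — and the reported value is
ln[(D³/v²ₚₑₐₖ)·C], which is invariant to time rescaling and amplitude
scaling and equals ln(102.4) ≈ 4.629 for a single minimum-jerk movement.
An amplitude-normalised variant ((D⁵/A²)·C, A = ∫|v|dt) is available via
`ProcessingParams(jerk_variant="amplitude")`. Smoothness values reported
by commercial analysis platforms depend on variant and scaling choices
that are not standardised, so the package validates this metric by its
closed-form anchor and properties (minimum-jerk value, scale invariances,
strict increase under velocity sub-peaks), not by matching platform
numbers. Numerical derivatives use second-order edge handling
(`np.gradient(..., edge_order=2)`); with first-order edges the squared
third derivative is visibly underestimated near the window edges.

Five trials per session are reduced to the mean of trials 2–4 in
execution order ("central trials"); a configurable fallback averages all
trials when a different count is supplied.

## Statistics

Reliability: ICC(2,k) from two-way ANOVA mean squares,
(MS_R − MS_E)/(MS_R + (MS_C − MS_E)/n), average measures, absolute
agreement. The "two-way mixed" and "two-way random" average-measures
absolute-agreement formulas coincide numerically, so one formula serves
both labels. The 95% CI is the standard F-based interval for the
single-measures coefficient (Satterthwaite denominator df) stepped up by
Spearman–Brown; in degenerate pure-noise samples the step-up can wrap
across its pole, in which case the interval is reordered and capped at 1.
Negative ICCs are reported as-is. SEM = SD·√(1 − ICC) uses, by default,
the between-subject SD of the first measurement column (`sd_source=
"pooled"` uses the flattened matrix); MDC₉₅ = SEM·√2·1.96. Verbal bands
close the gaps of the usual vocabulary at the upper bound of each
band: little < 0.16 ≤ low < 0.50 ≤ moderate < 0.70 ≤ high < 0.90 ≤ very
high.

Pre–post inference gates each outcome on a Shapiro–Wilk test of the
paired differences at α = 0.05 (the protocol's complementary visual
histogram inspection is not automatable; results carry a flag).
Parametric branch: paired t, mean ± SD, Cohen's d = t/√n. Nonparametric:
Wilcoxon signed-rank with Pratt zero handling, median ± IQR (type-7
quartiles), no effect size. Constant differences short-circuit to a
zero-variance result (p = 1). No multiplicity adjustment by default,
matching the single-group exploratory design this mirrors; Holm is
opt-in. The power analysis searches the noncentral-t power curve for the
smallest n with power ≥ target; one-tailed by default — the reading under
which d = 0.63737, α = 0.05, power 0.8 gives n = 17 (two-tailed gives 22).

## The synthetic-data generator

The generator is the package's test bed: it emulates the recording setup
with known ground truth rather than simulating physiology.

* **Hand path**: one-dimensional minimum-jerk position segments per
  transport phase (closed-form velocity/acceleration/jerk), a static
  drink phase, and a rest tail; accelerations are emitted analytically.
  Optional "velocity sub-peak" perturbations (windowed oscillations with
  analytic derivatives) degrade smoothness in a controlled way.
* **Angles**: cycloidal (half-cosine) ramps per phase. Unlike minimum-jerk
  ramps, cycloidal ramps arrive at the boundary with non-zero angular
  acceleration, so boundary extrema are locally quadratic and remain
  localisable within tens of milliseconds under 1° sensor noise — a
  minimum-jerk extremum is locally cubic and its argmax wanders by over
  100 ms under the same noise. Elbow extension peaks exactly at the two
  transport boundaries; shoulder elevation rises from the drink start and
  peaks at its end; scapular upward rotation is elevation divided by the
  configured scapulohumeral ratio (default 1.5), making SHR exact by
  construction; the other scapular DOFs follow configured per-phase ROM
  magnitudes with alternating direction; trunk channels are single bumps
  with configured signed peaks.
* **EMG**: per-phase %SVIC plateaus blended by 0.2 s smooth transitions
  centred on the boundaries, scaled by each muscle's SVIC amplitude. By
  default the envelope itself is emitted (with multiplicative noise); in
  `emg_mode="raw"` it amplitude-modulates a band-limited unit-RMS noise
  carrier so the full band-pass + RMS chain is exercised.
* **Variability**: one subject-level random offset per DOF and per muscle
  (shared across trials and sessions — this is what makes ICC > 0 and the
  pre–post design paired), i.i.d. trial-level parameter jitter, and white
  sensor noise (1° on angles, 0.05 m/s² on acceleration, 10% on EMG by
  default). Session M1 applies configured additive effects to generator
  parameters, never post hoc to metrics, so recovery tests traverse the
  whole pipeline.
* **Ground truth**: per trial, both the parameters actually used (after
  variability and effects) and the boundaries/metrics obtained by running
  the deterministic analysis chain on the trial's noise-free construction
  with exact normalisation references — i.e. what a perfect analyst would
  extract from noiseless signals. At zero noise the pipeline reproduces
  these values bit-for-bit; parameter-recovery checks against the
  configured values use small documented tolerances instead, because
  threshold-based event detection truncates, e.g., the drink-phase
  elevation ROM by the position accrued before the 5°/s initiation
  crossing (~0.2° at defaults), and envelope transitions contribute
  O(step/samples-per-phase) to phase means.

Default amplitudes (elbow extension 60°, shoulder elevation 45°, hand
displacement 0.45 m over ~1 s phases, scapular ROMs of 2–6°, EMG levels
of 8–25 %SVIC) are chosen once as realistic magnitudes for a light
self-paced drinking task. What the generator does **not** emulate: soft-
tissue artifact, sensor-fusion/orientation-estimation error, non-white
sensor noise, phase-duration variability between trials, muscle-activity
physiology, or any coupling between EMG and kinematics. Tests passing on
synthetic data therefore demonstrate the correctness and calibration of
the computation, not the biological validity of conclusions drawn from
real recordings.

## Problem sizes used in the test suite

The suite validates statistical calibration at sizes chosen to keep the
checks sharp but cheap: 200 seeded noisy trials for boundary recovery
(±50 ms criterion), 1000 random small matrices for the ICC oracle
(1e-10), 2000 metric-level null cohorts of n = 18 for type-I-error
calibration of the gate+test pipeline (band 0.04–0.06 at α = 0.05), and
an 8-subject full-pipeline cohort for effect recovery (−8 %SVIC within
±1). Monte-Carlo statistical nulls use metric-level cohorts drawn from
the same subject-effect + trial-noise model as the generator; full
signal-level cohorts are exercised at smaller counts.

## Known limitations

* Onset/end are defined on the low-pass-filtered acceleration; zero-phase
  filtering can place the onset a few ms before physical movement start.
* The smoothness value from integrated, 4 Hz-filtered acceleration is
  systematically below the analytic value of the underlying trajectory
  (the filter removes genuine jerk content); comparisons are meaningful
  within a fixed processing configuration only.
* Max-|·|-based metrics (ROM, trunk compensation) carry a positive
  extreme-value noise bias; the 6 Hz angle smoothing reduces it to a few
  tenths of a degree at 1° noise but does not remove it.
* The F-based ICC confidence interval is unreliable in degenerate
  samples (tiny studies, no subject variance); the point estimate is
  returned unclamped and can fall outside (−∞, 1] there.
* C3D / proprietary motion-platform import is an extension point; only
  the package's plain-text trial format is implemented.
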