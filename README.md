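# scapkin

Movement analysis of a functional **drinking task** for shoulder
rehabilitation research: scapular kinematics, surface EMG and
movement-quality metrics, with test–retest reliability and paired
pre–post inference.

The package is aimed at movement-analysis and rehabilitation researchers
who record a five-phase reach–drink–return task (reaching, forward
transport, drink, backward transport, returning) with 100 Hz joint
kinematics, a 2000 Hz hand accelerometer and 2000 Hz surface EMG of six
scapular muscles (UT, MT, LT, SAup/mid, SAlow, LS), and who want the full
computation — from raw channels to the statistics tables — reproducible
and testable. Because such recordings are rarely shareable, a first-class
synthetic-data generator emulates the recording setup with known ground
truth, so every stage can be validated end to end.

## What it computes

**Signal processing.** EMG: 2nd-order Butterworth band-pass 20–450 Hz
(zero-phase), sliding 100-sample RMS envelope, normalisation to a
submaximal isometric reference (three 5-s repetitions per muscle; activity
expressed in %SVIC). Hand acceleration: 4th-order Butterworth low-pass at
4 Hz (zero-phase). Rest posture: mean of the first 5 s of static
recording.

**Segmentation.** Task onset = earliest sustained excursion of hand
acceleration beyond ±0.3 m/s² around the rest mean; then
b1 = maximum elbow extension, b2 = initiation of shoulder elevation
(sustained angular velocity above 5°/s), b3 = maximum shoulder elevation,
b4 = the next elbow-extension maximum, and the end = sustained return of
the acceleration into the ±0.3 m/s² rest band.

**Metrics.** Per phase: range of motion (max − min) for the four scapular
degrees of freedom (abduction/adduction, elevation/depression,
upward/downward rotation, winging) and shoulder elevation; mean %SVIC per
muscle. Whole task: scapulohumeral rhythm
SHR = ROM(shoulder elevation)/ROM(scapular upward rotation) on the drink
phase; signed peak trunk compensation per trunk DOF; % time to peak hand
acceleration in the reaching phase normalised to task duration; global
movement smoothness as the log dimensionless jerk
ln[(D³/v²ₚₑₐₖ)·½∫j²dt] (a minimum-jerk segment gives exactly
360/1.875² = 102.4 before the log). Five trials per session; the three
central trials are averaged.

**Statistics.** Intra-rater test–retest reliability via the
average-measures absolute-agreement intraclass correlation
ICC(2,k) = (MS_R − MS_E)/(MS_R + (MS_C − MS_E)/n) with an F-based 95% CI,
SEM = SD·√(1 − ICC), MDC₉₅ = SEM·√2·1.96, and verbal bands
(little < 0.16 ≤ low < 0.50 ≤ moderate < 0.70 ≤ high < 0.90 ≤ very high).
Pre–post comparison per outcome with a Shapiro–Wilk-gated paired t-test
(Cohen's d = t/√n) or Wilcoxon signed-rank (median ± IQR), and a
design-stage power analysis for a paired design from the noncentral t
distribution.

## Worked example

```python
from scapkin import EffectSpec, GeneratorConfig, RunConfig, run_study

# a cohort of 8 subjects, 5 trials x 2 sessions, with a known intervention
# effect injected at follow-up: MT activity -8 %SVIC in the returning
# phase, resting scapular upward rotation +1.3 deg
eff = EffectSpec(emg={("MT", "returning"): -8.0}, rest={"scap_ur_dr": 1.3})
cfg = RunConfig(generator=GeneratorConfig(seed=1, n_subjects=8, effect_delta=eff))
res = run_study(cfg)
pp = res.prepost.set_index("outcome")
for k in ("emg_MT_returning", "rest_scap_ur_dr", "shr"):
    r = pp.loc[k]
    print(f"{k}: test={r.test} stat={r.statistic:.3f} p={r.p:.4g} "
          f"diff={r.difference:.3f}")
```

prints

```
emg_MT_returning: test=paired_t stat=-18.846 p=2.944e-07 diff=-8.247
rest_scap_ur_dr: test=paired_t stat=69.938 p=3.212e-11 diff=1.311
shr: test=paired_t stat=1.029 p=0.3379 diff=0.009
```

The two injected effects are recovered through the full signal chain
(−8.25 %SVIC against −8 injected; +1.31° against +1.3 injected) and
declared significant, while the untouched scapulohumeral rhythm is not.
The same result object carries the per-trial segmentation table
(e.g. `onset=5.996 b1=7.000 b2=7.890 b3=9.070 b4=10.010 end=11.096` for
the first trial) and the reliability table, e.g.
`emg_MT_returning: ICC=0.96 [0.88; 0.99] SEM=0.97 MDC95=2.70 (very high)`.

A command line mirrors the library
(`scapkin generate|process|segment|metrics|reliability|compare|power|run-all`);
`scapkin power --d 0.63737` prints `17`, the required paired-design sample
size at α = 0.05 (one-tailed) and power 0.80.

## Layout

- `src/scapkin/synthetic.py` — trial/SVIC/cohort generator with ground truth
- `src/scapkin/signal_processing.py` — filters, RMS envelope, %SVIC, rest position
- `src/scapkin/segmentation.py` — onset/end detection, five-phase events
- `src/scapkin/metrics.py` — ROM, SHR, smoothness, %TTP, trunk compensation, EMG means
- `src/scapkin/reliability.py` — ICC(2,k), SEM, MDC95, bands
- `src/scapkin/prepost.py` — gated paired tests, effect sizes, power
- `src/scapkin/io.py`, `pipeline.py`, `cli.py` — file formats, orchestration, CLI

See `docs/methods.md` for the model, assumptions, parameter choices and
known limitations.
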