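"""Synthetic drinking-task trials, SVIC recordings and paired cohorts.

The generator emulates a laboratory recording protocol for the task so
that every pipeline stage is testable with known ground truth:

* a pre-task rest segment, then five phases (reaching, forward transport,
  drink, backward transport, returning), then a tail rest;
* hand transport follows minimum-jerk position profiles (closed-form
  velocity/jerk references for the smoothness metric);
* angle channels follow cycloidal (half-cosine) ramps per phase, which end
  with non-zero angular acceleration so boundary extrema are sharply
  localisable by the event detectors (a minimum-jerk ramp would leave a
  locally-cubic, noise-fragile extremum);
* elbow extension peaks exactly at the reaching->forward-transport and
  backward-transport->returning boundaries; shoulder elevation rises from
  the drink-phase start and peaks at the drink->backward-transport
  boundary; scapular upward rotation is shoulder elevation divided by the
  scapulohumeral ratio;
* EMG is generated as per-phase %SVIC plateaus blended with smooth ramps,
  scaled by the muscle's SVIC amplitude, optionally amplitude-modulating a
  band-limited raw carrier;
* session M1 applies configured additive effects to generator parameters
  (not post hoc to metrics), so recovery tests exercise the full pipeline.

Per-trial ground truth records both the generator parameters actually used
(after subject/trial variability and session effects) and the boundary and
metric values obtained by running the deterministic analysis chain on the
trial's noise-free construction.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import ProcessingParams, analyze_trial
from .core import (MUSCLES, PHASES, SCAP_DOFS, TRUNK_DOFS, PhaseSegmentation,
                   ScapkinError, SvicRecording, TimeSeries, TrialRecording)
from .metrics import MetricSet

_SESSIONS = ("M0", "M1")


# ----------------------------------------------------------------- primitives

def minimum_jerk_position(tau: np.ndarray, amplitude: float) -> np.ndarray:
    """x(tau) = A (10 tau^3 - 15 tau^4 + 6 tau^5) on tau in [0, 1]."""
    return amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


def minimum_jerk_velocity(tau: np.ndarray, amplitude: float, duration: float) -> np.ndarray:
    return amplitude / duration * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)


def minimum_jerk_acceleration(tau: np.ndarray, amplitude: float, duration: float) -> np.ndarray:
    return amplitude / duration**2 * (60 * tau - 180 * tau**2 + 120 * tau**3)


def minimum_jerk_segment(amplitude: float, duration: float, rate: float) -> TimeSeries:
    """Minimum-jerk position profile from 0 to ``amplitude`` over ``duration``.

    Both endpoints are included (n = duration * rate + 1 samples); end
    velocity and acceleration are zero.  Peak speed is 1.875 A / D and peak
    acceleration occurs at tau = (3 - sqrt(3)) / 6 ~ 0.2113.
    """
    if duration <= 0 or rate <= 0:
        raise ScapkinError("duration and rate must be > 0")
    n = int(round(duration * rate))
    tau = np.arange(n + 1) / n
    return TimeSeries(minimum_jerk_position(tau, amplitude), rate, "m", "min_jerk")


def cycloid_ramp(tau: np.ndarray) -> np.ndarray:
    """Half-cosine smoothstep (1 - cos(pi tau)) / 2, clipped to [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * tau))


def _wiggle(u: np.ndarray, k: int) -> np.ndarray:
    """Windowed oscillation sin^2(pi u) sin(2 pi k u); zero value/slope at ends."""
    return np.sin(np.pi * u) ** 2 * np.sin(2 * np.pi * k * u)


def _wiggle_d1(u: np.ndarray, k: int) -> np.ndarray:
    return (np.pi * np.sin(2 * np.pi * u) * np.sin(2 * np.pi * k * u)
            + 2 * np.pi * k * np.sin(np.pi * u) ** 2 * np.cos(2 * np.pi * k * u))


def _wiggle_d2(u: np.ndarray, k: int) -> np.ndarray:
    return (2 * np.pi**2 * np.cos(2 * np.pi * u) * np.sin(2 * np.pi * k * u)
            + 4 * np.pi**2 * k * np.sin(2 * np.pi * u) * np.cos(2 * np.pi * k * u)
            - 4 * np.pi**2 * k**2 * np.sin(np.pi * u) ** 2 * np.sin(2 * np.pi * k * u))


# -------------------------------------------------------------- configuration

def _default_rom() -> dict[str, tuple[float, ...]]:
    # Per-phase ROM magnitudes (deg) for the independently driven scapular
    # DOFs; upward/downward rotation is slaved to shoulder elevation.
    return {
        "scap_ab_ad": (6.0, 4.0, 3.0, 4.0, 6.0),
        "scap_el_dep": (3.0, 2.0, 2.0, 2.0, 3.0),
        "scap_winging": (4.0, 3.0, 2.0, 3.0, 4.0),
    }


def _default_emg() -> dict[str, tuple[float, ...]]:
    # Per-phase mean activity (%SVIC); plausible magnitudes for a light
    # reach-and-drink task normalised to a submaximal reference.
    return {
        "UT": (20.0, 15.0, 10.0, 15.0, 20.0),
        "MT": (15.0, 20.0, 10.0, 20.0, 25.0),
        "LT": (15.0, 15.0, 10.0, 15.0, 25.0),
        "SAupmid": (20.0, 25.0, 15.0, 25.0, 20.0),
        "SAlow": (15.0, 20.0, 25.0, 20.0, 25.0),
        "LS": (10.0, 10.0, 8.0, 10.0, 18.0),
    }


@dataclass(frozen=True)
class EffectSpec:
    """Additive pre -> post (M0 -> M1) shifts applied to generator parameters.

    rom : {(channel, phase): delta_deg} added to the phase ROM magnitude.
    emg : {(muscle, phase): delta_pct} added to the phase %SVIC level.
    rest : {dof: delta_deg} added to the resting angle.
    smoothness_count / smoothness_amp : extra velocity sub-peaks
        (count and metres of path amplitude) superimposed on the transport
        phases at M1.
    """

    rom: dict = field(default_factory=dict)
    emg: dict = field(default_factory=dict)
    rest: dict = field(default_factory=dict)
    smoothness_count: int = 0
    smoothness_amp: float = 0.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions emulated by the generator.

    Rates, trial counts, the rest segment and the five-phase structure
    mirror the recording protocol (100 Hz kinematics, 2000 Hz EMG and hand
    acceleration, five trials per session, >= 5 s rest); amplitudes and
    activity levels are generator choices documented in the methods note.
    """

    seed: int = 0
    n_subjects: int = 10
    n_trials_per_subject: int = 5
    kin_rate: float = 100.0
    emg_rate: float = 2000.0
    rest_duration: float = 6.0
    tail_duration: float = 2.0
    phase_durations: tuple[float, ...] = (1.0, 0.9, 1.2, 0.9, 1.1)
    shr_ratio: float = 1.5
    elbow_rest: float = 10.0
    elbow_deltas: tuple[float, ...] = (60.0, -50.0, 0.0, 50.0, -60.0)
    elev_rest: float = 15.0
    elev_amplitude: float = 45.0
    rom_true: dict = field(default_factory=_default_rom)
    scap_rest: dict = field(default_factory=lambda: {
        "scap_ab_ad": 5.0, "scap_el_dep": 2.0, "scap_ur_dr": 5.0,
        "scap_winging": 3.0,
    })
    trunk_peaks: dict = field(default_factory=lambda: {
        "trunk_fw_flexion": -6.8, "trunk_ax_rotation": 5.3,
        "trunk_lat_flexion": 1.5,
    })
    emg_level_true: dict = field(default_factory=_default_emg)
    emg_rest_level: float = 3.0
    emg_transition_s: float = 0.2
    svic_amplitude: dict = field(default_factory=lambda: {m: 0.5 for m in MUSCLES})
    hand_deltas: tuple[float, ...] = (0.45, -0.30, 0.0, 0.30, -0.45)
    noise_sd_kin: float = 1.0
    noise_sd_emg: float = 0.1
    noise_sd_accel: float = 0.05
    rom_subject_sd: float = 1.0
    emg_subject_sd: float = 3.0
    rom_trial_sd: float = 0.5
    emg_trial_sd: float = 1.5
    smoothness_perturbation: tuple[int, float] = (0, 0.0)
    effect_delta: EffectSpec = field(default_factory=EffectSpec)
    emg_mode: str = "envelope"

    def __post_init__(self) -> None:
        if len(self.phase_durations) != 5:
            raise ScapkinError(
                f"phase_durations must have 5 entries, got {len(self.phase_durations)}"
            )
        if any(d <= 0 for d in self.phase_durations):
            raise ScapkinError("all phase durations must be > 0")
        if self.rest_duration < 5.0:
            raise ScapkinError("rest_duration must be >= 5 s")
        if self.kin_rate >= self.emg_rate:
            raise ScapkinError("kin_rate must be below emg_rate")
        if self.emg_rate % self.kin_rate:
            raise ScapkinError("emg_rate must be an integer multiple of kin_rate")
        if self.n_trials_per_subject < 3:
            raise ScapkinError("need at least 3 trials per subject")
        if self.n_subjects < 1:
            raise ScapkinError("need at least 1 subject")

    @property
    def movement_start(self) -> float:
        return self.rest_duration

    @property
    def movement_end(self) -> float:
        return self.rest_duration + sum(self.phase_durations)

    @property
    def total_duration(self) -> float:
        return self.movement_end + self.tail_duration

    def nominal_boundaries(self) -> tuple[float, ...]:
        """Construction phase edges (movement start, b1..b4, movement end)."""
        edges = np.concatenate(([0.0], np.cumsum(self.phase_durations)))
        return tuple(self.movement_start + edges)


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows about one trial.

    ``segmentation`` and ``metrics`` are the values the analysis chain
    produces on the trial's noise-free construction (what a perfect analyst
    would extract); ``rom``, ``emg_levels`` etc. are the generator
    parameters actually used for this trial after subject/trial variability
    and session effects.
    """

    segmentation: PhaseSegmentation
    nominal_boundaries: tuple[float, ...]
    metrics: MetricSet
    rom: dict
    emg_levels: dict
    shr_ratio: float
    trunk_peaks: dict
    rest_angles: dict
    ldj_analytic: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.rom.values()):
            raise ScapkinError("ground-truth ROM must be non-negative")


# ------------------------------------------------------------------- internals

def _subject_entropy(subject_id) -> int:
    return zlib.crc32(str(subject_id).encode("utf-8"))


def _subject_rng(config: GeneratorConfig, subject_id) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, _subject_entropy(subject_id), 7])
    )


def _trial_rng(config, subject_id, session, trial_index) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        [config.seed, _subject_entropy(subject_id),
         _SESSIONS.index(session) + 1, int(trial_index)]
    ))


@dataclass
class _TrialParams:
    """Resolved per-trial construction parameters."""

    elbow_deltas: np.ndarray
    elev_deltas: np.ndarray
    scap_deltas: dict
    rest_angles: dict
    emg_levels: dict
    trunk_peaks: dict
    hand_deltas: np.ndarray
    perturbation: tuple[int, float]


def _signed_adjust(deltas: np.ndarray, shift: float, floor: float = 0.5) -> np.ndarray:
    """Shift the magnitude of non-zero signed deltas, keeping their sign."""
    out = deltas.copy()
    nz = deltas != 0
    out[nz] = np.sign(deltas[nz]) * np.maximum(np.abs(deltas[nz]) + shift, floor)
    return out


def _resolve_params(config: GeneratorConfig, subject_id, session: str,
                    rng_trial: np.random.Generator) -> _TrialParams:
    rng_subj = _subject_rng(config, subject_id)
    # Subject-level random effects: one draw per DOF / muscle, shared by
    # every trial and both sessions of the subject (supports ICC > 0 and a
    # paired pre-post design).
    subj_rom = {ch: rng_subj.normal(0.0, config.rom_subject_sd)
                for ch in ("elbow", "elev", *config.rom_true)}
    subj_emg = {m: rng_subj.normal(0.0, config.emg_subject_sd) for m in MUSCLES}

    jit_rom = {ch: rng_trial.normal(0.0, config.rom_trial_sd) for ch in subj_rom}
    jit_emg = {m: rng_trial.normal(0.0, config.emg_trial_sd) for m in MUSCLES}

    eff = config.effect_delta if session == "M1" else EffectSpec()

    elbow = _signed_adjust(np.asarray(config.elbow_deltas, float),
                           subj_rom["elbow"] + jit_rom["elbow"])
    elev_amp = max(config.elev_amplitude + subj_rom["elev"] + jit_rom["elev"], 1.0)
    elev = np.array([0.0, 0.0, elev_amp, -elev_amp, 0.0])

    scap = {}
    signs = np.array([1.0, -1.0, 1.0, -1.0, 1.0])
    for dof, mags in config.rom_true.items():
        mags = np.asarray(mags, float)
        shift = subj_rom[dof] + jit_rom[dof]
        eff_shift = np.array([eff.rom.get((dof, ph), 0.0) for ph in PHASES])
        scap[dof] = signs * np.maximum(mags + shift + eff_shift, 0.5)
    for ph_i, ph in enumerate(PHASES):  # effects on the slaved/elbow channels
        elev[ph_i] = np.sign(elev[ph_i]) * max(
            abs(elev[ph_i]) + eff.rom.get(("shoulder_elevation", ph), 0.0), 0.0
        ) if elev[ph_i] else elev[ph_i]

    rest = {**config.scap_rest,
            "elbow_extension": config.elbow_rest,
            "shoulder_elevation": config.elev_rest,
            **{d: 0.0 for d in TRUNK_DOFS}}
    for dof, delta in eff.rest.items():
        rest[dof] = rest.get(dof, 0.0) + delta

    emg = {}
    for m in MUSCLES:
        levels = np.asarray(config.emg_level_true[m], float)
        shift = subj_emg[m] + jit_emg[m]
        eff_shift = np.array([eff.emg.get((m, ph), 0.0) for ph in PHASES])
        emg[m] = np.maximum(levels + shift + eff_shift, 0.5)

    k0, a0 = config.smoothness_perturbation
    perturbation = (k0 + eff.smoothness_count, a0 + eff.smoothness_amp)
    return _TrialParams(
        elbow_deltas=elbow, elev_deltas=elev, scap_deltas=scap,
        rest_angles=rest, emg_levels=emg, trunk_peaks=dict(config.trunk_peaks),
        hand_deltas=np.asarray(config.hand_deltas, float),
        perturbation=perturbation,
    )


def _piecewise_angle(t: np.ndarray, config: GeneratorConfig, rest_value: float,
                     deltas: np.ndarray) -> np.ndarray:
    """Rest level plus cycloidal per-phase ramps accumulating the deltas."""
    edges = config.nominal_boundaries()
    x = np.full_like(t, rest_value)
    level = rest_value
    for i in range(5):
        t0, t1 = edges[i], edges[i + 1]
        d = edges[i + 1] - edges[i]
        in_phase = (t >= t0) & (t < t1)
        x[in_phase] = level + deltas[i] * cycloid_ramp((t[in_phase] - t0) / d)
        level += deltas[i]
        x[t >= t1] = level
    return x


def _hand_kinematics(t: np.ndarray, config: GeneratorConfig,
                     params: _TrialParams) -> tuple[np.ndarray, np.ndarray]:
    """Analytic hand velocity and acceleration (1-D along the path)."""
    edges = config.nominal_boundaries()
    vel = np.zeros_like(t)
    acc = np.zeros_like(t)
    k, amp = params.perturbation
    for i in range(5):
        a_i = params.hand_deltas[i]
        t0, d = edges[i], edges[i + 1] - edges[i]
        if a_i == 0.0:
            continue
        in_phase = (t >= t0) & (t < edges[i + 1])
        tau = (t[in_phase] - t0) / d
        vel[in_phase] += minimum_jerk_velocity(tau, a_i, d)
        acc[in_phase] += minimum_jerk_acceleration(tau, a_i, d)
        if k > 0 and amp > 0 and i in (1, 3):  # transport phases
            vel[in_phase] += amp / d * _wiggle_d1(tau, k)
            acc[in_phase] += amp / d**2 * _wiggle_d2(tau, k)
    return vel, acc


def _emg_envelope_pct(t: np.ndarray, config: GeneratorConfig,
                      levels: np.ndarray) -> np.ndarray:
    """%SVIC envelope: rest level, per-phase plateaus, smooth transitions."""
    edges = config.nominal_boundaries()
    seq = np.concatenate(([config.emg_rest_level], levels, [config.emg_rest_level]))
    env = np.full_like(t, config.emg_rest_level)
    w = config.emg_transition_s
    for j, t_edge in enumerate(edges):
        step = seq[j + 1] - seq[j]
        env += step * cycloid_ramp((t - t_edge) / w + 0.5)
    return env


def _analytic_ldj(config: GeneratorConfig, params: _TrialParams) -> float:
    """Smoothness of the noise-free hand trajectory over the nominal task span.

    Computed from the closed-form velocity sampled densely, independent of
    the pipeline's acceleration-integration route.
    """
    from .metrics import dimensionless_jerk  # local import to avoid cycles at init

    rate = config.emg_rate
    t = np.arange(int(round(config.total_duration * rate))) / rate
    vel, _ = _hand_kinematics(t, config, params)
    series = TimeSeries(vel, rate, "m/s", "hand_velocity_true")
    value = dimensionless_jerk(series, (config.movement_start, config.movement_end))
    return float(np.log(value))


# ------------------------------------------------------------------ generation

def _build_noise_free(config: GeneratorConfig, params: _TrialParams,
                      subject_id, session: str, trial_index: int) -> TrialRecording:
    n_kin = int(round(config.total_duration * config.kin_rate))
    n_hf = int(round(config.total_duration * config.emg_rate))
    t_kin = np.arange(n_kin) / config.kin_rate
    t_hf = np.arange(n_hf) / config.emg_rate

    kin = {}
    kin["elbow_extension"] = _piecewise_angle(
        t_kin, config, params.rest_angles["elbow_extension"], params.elbow_deltas)
    elev = _piecewise_angle(
        t_kin, config, params.rest_angles["shoulder_elevation"], params.elev_deltas)
    kin["shoulder_elevation"] = elev
    kin["scap_ur_dr"] = (params.rest_angles["scap_ur_dr"]
                         + (elev - params.rest_angles["shoulder_elevation"])
                         / config.shr_ratio)
    for dof in ("scap_ab_ad", "scap_el_dep", "scap_winging"):
        kin[dof] = _piecewise_angle(t_kin, config, params.rest_angles[dof],
                                    params.scap_deltas[dof])
    t0, t1 = config.movement_start, config.movement_end
    u = np.clip((t_kin - t0) / (t1 - t0), 0.0, 1.0)
    for dof in TRUNK_DOFS:
        kin[dof] = params.rest_angles[dof] + params.trunk_peaks[dof] * np.sin(np.pi * u) ** 2

    _, accel = _hand_kinematics(t_hf, config, params)
    hf = {"hand_accel": accel}
    for m in MUSCLES:
        pct = _emg_envelope_pct(t_hf, config, params.emg_levels[m])
        hf[f"emg_{m}"] = pct / 100.0 * config.svic_amplitude[m]

    return TrialRecording(
        kin=pd.DataFrame(kin), hf=pd.DataFrame(hf),
        kin_rate=config.kin_rate, hf_rate=config.emg_rate,
        rest_duration=config.rest_duration, emg_mode="envelope",
        subject=str(subject_id), session=session, trial=int(trial_index),
    )


def _ground_truth(config: GeneratorConfig, params: _TrialParams,
                  clean: TrialRecording,
                  processing: ProcessingParams) -> GroundTruth:
    refs = dict(config.svic_amplitude)
    seg, metric_set = analyze_trial(clean, refs, processing)
    rom = {}
    for i, ph in enumerate(PHASES):
        rom[("elbow_extension", ph)] = abs(params.elbow_deltas[i])
        rom[("shoulder_elevation", ph)] = abs(params.elev_deltas[i])
        rom[("scap_ur_dr", ph)] = abs(params.elev_deltas[i]) / config.shr_ratio
        for dof in params.scap_deltas:
            rom[(dof, ph)] = abs(params.scap_deltas[dof][i])
    emg_levels = {(m, ph): float(params.emg_levels[m][i])
                  for m in MUSCLES for i, ph in enumerate(PHASES)}
    return GroundTruth(
        segmentation=seg,
        nominal_boundaries=config.nominal_boundaries(),
        metrics=metric_set,
        rom=rom,
        emg_levels=emg_levels,
        shr_ratio=config.shr_ratio,
        trunk_peaks=dict(params.trunk_peaks),
        rest_angles=dict(params.rest_angles),
        ldj_analytic=_analytic_ldj(config, params),
    )


def _band_limited_carrier(rng: np.random.Generator, n: int, rate: float) -> np.ndarray:
    """Unit-RMS noise carrier band-limited to the surface-EMG band."""
    from .signal_processing import bandpass_emg

    white = rng.standard_normal(n)
    carrier = bandpass_emg(TimeSeries(white, rate, "", "carrier")).samples
    return carrier / np.sqrt(np.mean(carrier**2))


def generate_trial(config: GeneratorConfig, subject_id, trial_index: int,
                   session: str = "M0",
                   processing: ProcessingParams | None = None,
                   ) -> tuple[TrialRecording, GroundTruth]:
    """One task execution plus its ground truth.

    Identical (config, subject, trial, session) always yields bit-identical
    output.  Session ``"M1"`` applies ``config.effect_delta`` to the
    generator parameters before construction.
    """
    if session not in _SESSIONS:
        raise ScapkinError(f"session must be one of {_SESSIONS}, got {session!r}")
    processing = processing or ProcessingParams()
    rng = _trial_rng(config, subject_id, session, trial_index)
    params = _resolve_params(config, subject_id, session, rng)
    clean = _build_noise_free(config, params, subject_id, session, trial_index)
    truth = _ground_truth(config, params, clean, processing)

    kin = clean.kin.copy()
    if config.noise_sd_kin > 0:
        kin += rng.normal(0.0, config.noise_sd_kin, size=kin.shape)
    hf = clean.hf.copy()
    if config.noise_sd_accel > 0:
        hf["hand_accel"] += rng.normal(0.0, config.noise_sd_accel, len(hf))
    for m in MUSCLES:
        col = f"emg_{m}"
        env = hf[col].to_numpy()
        if config.noise_sd_emg > 0:
            env = np.maximum(env * (1.0 + config.noise_sd_emg
                                    * rng.standard_normal(env.size)), 0.0)
        if config.emg_mode == "raw":
            env = env * _band_limited_carrier(rng, env.size, config.emg_rate)
        hf[col] = env

    noisy = replace(clean, kin=kin, hf=hf, emg_mode=config.emg_mode)
    return noisy, truth


def generate_svic(config: GeneratorConfig, muscle: str,
                  subject_id="S01", rep_duration: float = 5.0) -> SvicRecording:
    """Three submaximal isometric repetitions for one muscle.

    Each repetition is a constant envelope at the muscle's reference
    amplitude with multiplicative noise; in raw mode the envelope modulates
    a band-limited carrier.
    """
    if muscle not in MUSCLES:
        raise ScapkinError(f"unknown muscle {muscle!r}")
    amp = config.svic_amplitude[muscle]
    reps = []
    n = int(round(rep_duration * config.emg_rate))
    for rep in range(3):
        rng = np.random.default_rng(np.random.SeedSequence(
            [config.seed, _subject_entropy(subject_id), 99,
             MUSCLES.index(muscle), rep]))
        env = np.full(n, amp)
        if config.noise_sd_emg > 0:
            env = np.maximum(env * (1.0 + config.noise_sd_emg
                                    * rng.standard_normal(n)), 0.0)
        if config.emg_mode == "raw":
            env = env * _band_limited_carrier(rng, n, config.emg_rate)
        reps.append(TimeSeries(env, config.emg_rate,
                               "V" if config.emg_mode == "raw" else "envelope",
                               f"svic_{muscle}_rep{rep + 1}"))
    return SvicRecording(muscle=muscle, repetitions=tuple(reps))


@dataclass
class Cohort:
    """Paired M0/M1 dataset with the ground-truth ledger."""

    config: GeneratorConfig
    trials: dict            # (subject, session) -> list[(TrialRecording, GroundTruth)]
    svic: dict              # subject -> {muscle: SvicRecording}
    ledger: pd.DataFrame    # long table of injected effects and true values

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.trials})


def generate_cohort(config: GeneratorConfig,
                    processing: ProcessingParams | None = None) -> Cohort:
    """Per subject: n trials x 2 sessions plus an SVIC set.

    The ledger records, for every trial, the true metric values of its
    noise-free construction and, once per configured effect, the injected
    pre -> post shift.
    """
    processing = processing or ProcessingParams()
    trials: dict = {}
    svic: dict = {}
    rows = []
    for i in range(config.n_subjects):
        subject = f"S{i + 1:02d}"
        svic[subject] = {m: generate_svic(config, m, subject) for m in MUSCLES}
        for session in _SESSIONS:
            bundle = []
            for trial_index in range(1, config.n_trials_per_subject + 1):
                rec, truth = generate_trial(config, subject, trial_index,
                                            session, processing)
                bundle.append((rec, truth))
                for key, value in truth.metrics.values.items():
                    rows.append((subject, session, trial_index, "metric",
                                 key, value))
            trials[(subject, session)] = bundle
    eff = config.effect_delta
    for (dof, ph), d in eff.rom.items():
        rows.append(("*", "M1", 0, "effect", f"rom_{dof}_{ph}", d))
    for (m, ph), d in eff.emg.items():
        rows.append(("*", "M1", 0, "effect", f"emg_{m}_{ph}", d))
    for dof, d in eff.rest.items():
        rows.append(("*", "M1", 0, "effect", f"rest_{dof}", d))
    ledger = pd.DataFrame(
        rows, columns=["subject", "session", "trial", "kind", "key", "value"])
    return Cohort(config=config, trials=trials, svic=svic, ledger=ledger)
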