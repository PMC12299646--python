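"""Per-phase kinematic/EMG metrics and whole-task movement-quality metrics.

Windows are inclusive of both boundary samples, so an extremum that defines
a phase boundary (e.g. peak shoulder elevation at the drink -> backward
transport transition) belongs to both adjacent phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .core import (PHASES, SCAP_DOFS, TRUNK_DOFS, MUSCLES, PhaseSegmentation,
                   ScapkinError, TimeSeries, TrialRecording)
from .signal_processing import rest_position

#: Supported dimensionless-jerk normalisations.
JERK_VARIANTS = ("speed", "amplitude")

#: Denominator floor (deg) below which the scapulohumeral ratio is undefined.
SHR_DEGENERACY_FLOOR_DEG = 0.5


@dataclass
class MetricSet:
    """Flat name -> value map of all per-trial (or trial-averaged) metrics.

    Keys: ``rest_<dof>``, ``rom_<channel>_<phase>``, ``emg_<muscle>_<phase>``,
    ``shr``, ``trunk_comp_<dof>``, ``ttp_pct``, ``ldj``.
    """

    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def keys(self):
        return self.values.keys()

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=float)


def range_of_motion(angle: TimeSeries, window: tuple[float, float]) -> float:
    """max - min of the angle inside the (inclusive) window, in degrees."""
    seg = angle.crop(*window)
    return float(np.max(seg.samples) - np.min(seg.samples))


def scapulohumeral_rhythm(shoulder_elev: TimeSeries, scap_ur: TimeSeries,
                          window: tuple[float, float]) -> float:
    """Shoulder-elevation ROM over scapular upward-rotation ROM.

    Evaluated on the drink-phase elevation window by the pipeline; the
    lowering portion is symmetric for a coupled rhythm.
    """
    scap_rom = range_of_motion(scap_ur, window)
    if scap_rom < SHR_DEGENERACY_FLOOR_DEG:
        raise ScapkinError(
            f"scapular upward-rotation ROM {scap_rom:.3f} deg below the "
            f"{SHR_DEGENERACY_FLOOR_DEG} deg degeneracy floor"
        )
    return range_of_motion(shoulder_elev, window) / scap_rom


def dimensionless_jerk(velocity: TimeSeries, window: tuple[float, float],
                       variant: str = "speed") -> float:
    """Dimensionless squared-jerk integral of a 1-D velocity profile.

    The jerk cost is C = (1/2) int j(t)^2 dt with j the derivative of
    acceleration (third derivative of position); the conventional 1/2
    makes C = 360 A^2 / D^5 for a minimum-jerk segment.  The ``speed``
    variant (default) normalises by duration and peak speed,
    DJ = (D^3 / v_peak^2) C, and is invariant to time rescaling and to
    amplitude scaling of the velocity profile; a single minimum-jerk
    segment gives DJ = 360 / 1.875^2 = 102.4 exactly.  The ``amplitude``
    variant normalises by the travelled amplitude A = int |v| dt instead,
    DJ = (D^5 / A^2) C, giving 360 for a minimum-jerk segment.  Larger
    values mean less smooth movement.
    """
    if variant not in JERK_VARIANTS:
        raise ScapkinError(f"unknown jerk variant {variant!r}; use {JERK_VARIANTS}")
    v = velocity.crop(*window)
    if v.n < 5:
        raise ScapkinError("window too short for jerk estimation")
    duration = (v.n - 1) / v.rate
    dt = 1.0 / v.rate
    accel = np.gradient(v.samples, dt, edge_order=2)
    jerk = np.gradient(accel, dt, edge_order=2)
    cost = 0.5 * float(np.trapezoid(jerk ** 2, dx=dt))
    if variant == "speed":
        v_peak = float(np.max(np.abs(v.samples)))
        if v_peak <= 0:
            raise ScapkinError("zero peak speed in jerk window")
        return duration ** 3 / v_peak ** 2 * cost
    amplitude = float(np.trapezoid(np.abs(v.samples), dx=dt))
    if amplitude <= 0:
        raise ScapkinError("zero movement amplitude in jerk window")
    return duration ** 5 / amplitude ** 2 * cost


def log_dimensionless_jerk(velocity: TimeSeries, window: tuple[float, float],
                           variant: str = "speed") -> float:
    """Natural log of :func:`dimensionless_jerk` (the reported smoothness value)."""
    return float(np.log(dimensionless_jerk(velocity, window, variant)))


def hand_velocity(accel: TimeSeries, window: tuple[float, float]) -> TimeSeries:
    """Hand velocity over the task window by trapezoidal integration.

    The sensor provides acceleration only; integration drift is controlled
    by removing the linear trend that would leave a non-zero final velocity
    (the hand is at rest at both task ends).
    """
    a = accel.crop(*window)
    v = cumulative_trapezoid(a.samples, dx=1.0 / a.rate, initial=0.0)
    ramp = np.linspace(0.0, v[-1], v.size)
    return TimeSeries(v - ramp, a.rate, "m/s", "hand_velocity")


def time_to_peak_percent(hand_accel: TimeSeries, reaching: tuple[float, float],
                         task: tuple[float, float]) -> float:
    """Time of peak |acceleration| in the reaching phase, as % of task duration.

    Ties are broken toward the earliest sample.
    """
    onset, end = task
    if end <= onset:
        raise ScapkinError("task window must have positive duration")
    seg = hand_accel.crop(*reaching)
    if seg.n == 0:
        raise ScapkinError("empty reaching phase")
    i_peak = int(np.argmax(np.abs(seg.samples)))
    t_peak = hand_accel.index_at(reaching[0]) / hand_accel.rate + i_peak / hand_accel.rate
    return 100.0 * (t_peak - onset) / (end - onset)


def trunk_compensation(trunk_angle: TimeSeries, window: tuple[float, float],
                       neutral: float) -> float:
    """Signed peak deviation from the neutral (rest) posture within the window."""
    seg = trunk_angle.crop(*window)
    dev = seg.samples - neutral
    return float(dev[int(np.argmax(np.abs(dev)))])


def emg_phase_mean(envelope_pct: TimeSeries, window: tuple[float, float]) -> float:
    """Arithmetic mean of the %SVIC envelope inside the phase window."""
    seg = envelope_pct.crop(*window)
    return float(np.mean(seg.samples))


def compute_trial_metrics(trial: TrialRecording, seg: PhaseSegmentation,
                          emg_pct: dict[str, TimeSeries],
                          jerk_variant: str = "speed") -> MetricSet:
    """All metrics for one segmented trial.

    ``emg_pct`` maps muscle -> %SVIC envelope on the kinematic time base
    (see :func:`scapkin.pipeline.process_trial`).
    """
    m: dict[str, float] = {}
    task = (seg.onset, seg.end)

    for dof in SCAP_DOFS:
        m[f"rest_{dof}"] = rest_position(trial.angle(dof))
    for channel in SCAP_DOFS + ("shoulder_elevation",):
        angle = trial.angle(channel)
        for phase in PHASES:
            m[f"rom_{channel}_{phase}"] = range_of_motion(
                angle, seg.phase_window(phase)
            )
    for muscle in MUSCLES:
        env = emg_pct[muscle]
        for phase in PHASES:
            m[f"emg_{muscle}_{phase}"] = emg_phase_mean(env, seg.phase_window(phase))

    m["shr"] = scapulohumeral_rhythm(
        trial.angle("shoulder_elevation"), trial.angle("scap_ur_dr"),
        seg.phase_window("drink"),
    )
    for dof in TRUNK_DOFS:
        angle = trial.angle(dof)
        m[f"trunk_comp_{dof}"] = trunk_compensation(
            angle, task, neutral=rest_position(angle)
        )
    accel = trial.accel()
    m["ttp_pct"] = time_to_peak_percent(accel, seg.phase_window("reaching"), task)
    m["ldj"] = log_dimensionless_jerk(hand_velocity(accel, task),
                                      (0.0, seg.end - seg.onset), jerk_variant)
    return MetricSet(m)


def aggregate_central_trials(metric_sets: list[MetricSet],
                             on_count_mismatch: str = "error") -> MetricSet:
    """Element-wise mean of the three central trials (trials 2-4 of 5).

    ``metric_sets`` must be in execution order.  With
    ``on_count_mismatch="mean"`` any other count is averaged wholesale
    instead of raising.
    """
    if len(metric_sets) != 5:
        if on_count_mismatch == "mean":
            central = metric_sets
        else:
            raise ScapkinError(
                f"expected 5 trials in execution order, got {len(metric_sets)}"
            )
    else:
        central = metric_sets[1:4]
    if not central:
        raise ScapkinError("no trials to aggregate")
    keys = central[0].values.keys()
    return MetricSet(
        {k: float(np.mean([ms[k] for ms in central])) for k in keys}
    )
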