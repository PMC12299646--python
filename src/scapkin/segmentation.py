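"""Task onset/end detection and five-phase segmentation of the drinking task.

Onset and end are detected on the (low-pass-filtered) hand-acceleration
channel at its native rate; the interior boundaries are kinematic events on
the 100 Hz angle channels:

* b1 - reaching -> forward transport: maximum elbow extension,
* b2 - forward transport -> drink: initiation of shoulder elevation,
* b3 - drink -> backward transport: maximum shoulder elevation,
* b4 - backward transport -> returning: a new elbow-extension maximum.

The acceleration rule (|a - rest mean| vs 0.3 m/s^2) is an absolute
threshold in m/s^2; rescaling the acceleration units rescales the effective
sensitivity.  Sustain windows and the elevation-velocity criterion are
package operationalisations (the event definitions state thresholds only)
and are configurable through :class:`SegmentationParams`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import PhaseSegmentation, ScapkinError, TimeSeries, TrialRecording


class SegmentationError(ScapkinError):
    """A required boundary event could not be found."""

    def __init__(self, boundary: str, message: str):
        self.boundary = boundary
        super().__init__(f"segmentation failed at {boundary}: {message}")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable constants of the event detectors.

    accel_threshold_ms2 : onset/end band half-width around the rest mean.
    onset_sustain_s / end_sustain_s : minimum time the acceleration must stay
        outside / inside the band for a crossing to count (suppresses
        single-sample noise crossings).
    elev_velocity_threshold_dps : angular velocity (deg/s) defining
        "initiation of shoulder elevation", sustained for elev_sustain_s.
    event_lowpass_hz / event_lowpass_order : zero-phase Butterworth smoothing
        applied to angle channels before event detection only (metrics are
        computed on the unsmoothed angles).  2 Hz retains the <1 Hz content
        of self-paced reach-and-drink movements while suppressing wide-band
        sensor noise enough to localise extrema to a few tens of ms.
    rest_margin_s : tail of the rest segment excluded from the rest mean so
        zero-phase filtering smear from movement start cannot leak into it.
    """

    accel_threshold_ms2: float = 0.3
    onset_sustain_s: float = 0.05
    end_sustain_s: float = 0.20
    elev_velocity_threshold_dps: float = 5.0
    elev_sustain_s: float = 0.10
    event_lowpass_hz: float = 2.0
    event_lowpass_order: int = 2
    rest_margin_s: float = 0.5


def _first_sustained(flags: np.ndarray, n_sustain: int, start: int = 0) -> int:
    """First index >= start opening a run of >= n_sustain consecutive True."""
    flags = flags.astype(np.int64)
    if n_sustain <= 1:
        hits = np.flatnonzero(flags[start:])
        return start + hits[0] if hits.size else -1
    cs = np.concatenate(([0], np.cumsum(flags)))
    window_sums = cs[n_sustain:] - cs[:-n_sustain]  # sum over [i, i+n)
    hits = np.flatnonzero(window_sums[start:] == n_sustain)
    return start + hits[0] if hits.size else -1


def smooth_for_events(angle: TimeSeries, params: SegmentationParams) -> TimeSeries:
    """Zero-phase low-pass used only for event localisation."""
    sos = sps.butter(
        params.event_lowpass_order, params.event_lowpass_hz,
        btype="lowpass", fs=angle.rate, output="sos",
    )
    return angle.with_samples(sps.sosfiltfilt(sos, angle.samples))


def rest_mean_accel(accel: TimeSeries, rest_duration: float,
                    params: SegmentationParams | None = None) -> float:
    """Mean acceleration over the rest segment (minus a trailing margin)."""
    params = params or SegmentationParams()
    n = int(round(max(rest_duration - params.rest_margin_s, 1.0) * accel.rate))
    if n < accel.rate:
        raise ScapkinError("rest window must cover at least 1 s")
    return float(np.mean(accel.samples[:n]))


def detect_onset(accel: TimeSeries, rest_window: float,
                 params: SegmentationParams | None = None) -> float:
    """Earliest sustained excursion of |a - rest mean| beyond the threshold.

    ``rest_window`` is the duration of the pre-movement rest segment used
    for the rest mean (>= 1 s of usable data required).
    """
    params = params or SegmentationParams()
    rest_mean = rest_mean_accel(accel, rest_window, params)
    dev = np.abs(accel.samples - rest_mean) > params.accel_threshold_ms2
    n_sustain = max(1, int(round(params.onset_sustain_s * accel.rate)))
    i = _first_sustained(dev, n_sustain)
    if i < 0:
        raise SegmentationError("onset", "acceleration never leaves the rest band")
    return i / accel.rate


def detect_end(accel: TimeSeries, after: float, rest_mean: float,
               params: SegmentationParams | None = None) -> float:
    """Earliest sustained return of the acceleration into the rest band after ``after``."""
    params = params or SegmentationParams()
    inside = np.abs(accel.samples - rest_mean) <= params.accel_threshold_ms2
    n_sustain = max(1, int(round(params.end_sustain_s * accel.rate)))
    start = int(np.ceil(after * accel.rate - 1e-9)) + 1
    if start >= accel.n:
        raise SegmentationError("end", "'after' lies beyond the recording")
    i = _first_sustained(inside, n_sustain, start=start)
    if i < 0:
        raise SegmentationError("end", "acceleration never returns to the rest band")
    return i / accel.rate


def _argmax_interior(x: np.ndarray, i0: int, i1: int, boundary: str) -> int:
    """Earliest argmax of x over [i0, i1]; must not sit on the window edge."""
    if i1 <= i0:
        raise SegmentationError(boundary, f"empty search window [{i0}, {i1}]")
    i = i0 + int(np.argmax(x[i0 : i1 + 1]))
    if i in (i0, i1):
        raise SegmentationError(
            boundary, "no interior extremum (monotone signal in search window)"
        )
    return i


def segment_phases(trial: TrialRecording,
                   params: SegmentationParams | None = None) -> PhaseSegmentation:
    """Detect the onset, the four interior boundaries and the end of the task.

    The hand-acceleration channel of ``trial`` is expected to be low-pass
    filtered already (see :func:`scapkin.signal_processing.lowpass_accel`).
    """
    params = params or SegmentationParams()
    accel = trial.accel()
    rest_mean = rest_mean_accel(accel, trial.rest_duration, params)
    onset = detect_onset(accel, trial.rest_duration, params)

    kr = trial.kin_rate
    elbow = smooth_for_events(trial.angle("elbow_extension"), params).samples
    elev = smooth_for_events(trial.angle("shoulder_elevation"), params).samples
    n_kin = elbow.size
    i_on = int(np.ceil(onset * kr - 1e-9))

    # (c) maximum shoulder elevation; searched to the end of the recording
    # because the task end itself is only defined after b4.
    i_b3 = _argmax_interior(elev, i_on, n_kin - 1, "b3")

    # (a) maximum elbow extension before the drink phase.
    i_b1 = _argmax_interior(elbow, i_on, i_b3, "b1")

    # (b) initiation of shoulder elevation: sustained positive velocity.
    vel = np.gradient(elev) * kr
    n_sustain = max(1, int(round(params.elev_sustain_s * kr)))
    i_b2 = _first_sustained(
        vel > params.elev_velocity_threshold_dps, n_sustain, start=i_b1 + 1
    )
    if i_b2 < 0 or i_b2 >= i_b3:
        raise SegmentationError("b2", "shoulder elevation never initiates")

    # (d) the next elbow-extension maximum after the elevation peak.
    i_b4 = _argmax_interior(elbow, i_b3, n_kin - 1, "b4")

    end = detect_end(accel, i_b4 / kr, rest_mean, params)

    try:
        return PhaseSegmentation(
            onset=onset, b1=i_b1 / kr, b2=i_b2 / kr, b3=i_b3 / kr,
            b4=i_b4 / kr, end=end,
        )
    except ScapkinError as exc:  # ordering violation
        raise SegmentationError("ordering", str(exc)) from exc
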