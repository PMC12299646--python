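"""Filtering, envelope extraction, SVIC normalisation and rest position.

All filters are applied zero-phase (forward-backward, :func:`scipy.signal.filtfilt`)
so that event timing downstream is not delayed; the effective filter order is
therefore doubled relative to the nominal design order.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import ScapkinError, SvicRecording, TimeSeries

#: EMG band-pass design: 2nd-order Butterworth, 20-450 Hz.
EMG_BAND_HZ = (20.0, 450.0)
EMG_BAND_ORDER = 2

#: Acceleration low-pass design: 4th-order Butterworth, 4 Hz.
ACCEL_LOWPASS_HZ = 4.0
ACCEL_LOWPASS_ORDER = 4

#: Sliding-window RMS length, in samples at the EMG rate.
RMS_WINDOW_SAMPLES = 100


def bandpass_emg(raw: TimeSeries, band: tuple[float, float] = EMG_BAND_HZ,
                 order: int = EMG_BAND_ORDER) -> TimeSeries:
    """Zero-phase Butterworth band-pass of a raw EMG channel.

    Requires a sampling rate comfortably above twice the upper band edge
    (rate > 900 Hz for the default 20-450 Hz band).
    """
    if raw.rate <= 2 * band[1]:
        raise ScapkinError(
            f"EMG rate {raw.rate} Hz too low for a {band[1]} Hz band edge"
        )
    sos = sps.butter(order, band, btype="bandpass", fs=raw.rate, output="sos")
    out = sps.sosfiltfilt(sos, raw.samples)
    return raw.with_samples(out)


def lowpass_accel(raw: TimeSeries, cutoff: float = ACCEL_LOWPASS_HZ,
                  order: int = ACCEL_LOWPASS_ORDER) -> TimeSeries:
    """Zero-phase Butterworth low-pass of the hand-acceleration channel."""
    if raw.rate <= 2 * cutoff:
        raise ScapkinError(f"rate {raw.rate} Hz too low for a {cutoff} Hz cutoff")
    sos = sps.butter(order, cutoff, btype="lowpass", fs=raw.rate, output="sos")
    return raw.with_samples(sps.sosfiltfilt(sos, raw.samples))


def rms_envelope(filtered: TimeSeries, window: int = RMS_WINDOW_SAMPLES) -> TimeSeries:
    """Sliding-window RMS amplitude envelope.

    The output has the same length as the input: the squared signal is
    reflect-padded by half a window at each edge and box-car averaged, which
    centre-aligns the window and keeps the envelope on the same time base as
    the kinematic channels.
    """
    if window < 1:
        raise ScapkinError("RMS window must be >= 1 sample")
    if filtered.n < window:
        raise ScapkinError(
            f"signal ({filtered.n} samples) shorter than RMS window ({window})"
        )
    sq = filtered.samples ** 2
    left = window // 2
    right = window - 1 - left
    padded = np.pad(sq, (left, right), mode="reflect")
    kernel = np.ones(window) / window
    mean_sq = np.convolve(padded, kernel, mode="valid")
    return filtered.with_samples(np.sqrt(np.maximum(mean_sq, 0.0)))


def svic_reference(svic: SvicRecording, central_s: float = 3.0,
                   already_envelope: bool = True) -> float:
    """Normalisation reference amplitude for one muscle.

    Mean over the three repetitions of the mean amplitude envelope of each
    repetition's central ``central_s`` seconds (ramp-up/-down excluded).  If
    ``already_envelope`` is false the band-pass + RMS chain is applied first.
    """
    rep_means = []
    for rep in svic.repetitions:
        env = rep if already_envelope else rms_envelope(bandpass_emg(rep))
        n = env.n
        margin = max(0, int(round((env.duration - central_s) / 2 * env.rate)))
        central = env.samples[margin : n - margin] if margin else env.samples
        rep_means.append(float(np.mean(central)))
    ref = float(np.mean(rep_means))
    if ref < 1e-12:
        raise ScapkinError(
            f"degenerate SVIC reference ({ref:g}) for muscle {svic.muscle}"
        )
    return ref


def normalize_to_svic(envelope: TimeSeries, reference: float) -> TimeSeries:
    """Express an amplitude envelope in %SVIC (samples * 100 / reference)."""
    if reference <= 0:
        raise ScapkinError(f"SVIC reference must be > 0, got {reference}")
    out = envelope.with_samples(envelope.samples * (100.0 / reference))
    return TimeSeries(out.samples, envelope.rate, "%SVIC", envelope.label)


def downsample_block_mean(series: TimeSeries, target_rate: float) -> TimeSeries:
    """Carry an envelope to a lower rate by averaging non-overlapping blocks.

    The source rate must be an integer multiple of the target rate (20 blocks
    of the 2000 Hz envelope per 100 Hz kinematic sample by default).
    """
    factor = series.rate / target_rate
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ScapkinError(
            f"rate {series.rate} is not an integer multiple of {target_rate}"
        )
    factor = int(round(factor))
    n_blocks = series.n // factor
    blocks = series.samples[: n_blocks * factor].reshape(n_blocks, factor)
    return TimeSeries(blocks.mean(axis=1), target_rate, series.units, series.label)


def rest_position(angle: TimeSeries, rest_window: float = 5.0) -> float:
    """Mean of the first ``rest_window`` seconds of a static angle recording."""
    n_needed = int(round(rest_window * angle.rate))
    if angle.n < n_needed:
        raise ScapkinError(
            f"recording covers {angle.duration:.2f} s < {rest_window} s rest window"
        )
    return float(np.mean(angle.samples[:n_needed]))
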