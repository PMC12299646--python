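"""Core containers shared by every stage of the pipeline.

Sign conventions follow the convention block written into every trial file:
scapular abduction (+) / adduction (-), elevation (+) / depression (-),
upward rotation (+) / downward rotation (-), winging (+); trunk forward
flexion (-) / extension (+); trunk axial rotation and lateral flexion (+)
toward the assessed side; elbow angle is extension-signed (extension +).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Five phases of the drinking task, in execution order.
PHASES = ("reaching", "forward_transport", "drink", "backward_transport", "returning")

#: Kinematic channels recorded at the (100 Hz) kinematic rate.
KIN_CHANNELS = (
    "elbow_extension",
    "shoulder_elevation",
    "scap_ab_ad",
    "scap_el_dep",
    "scap_ur_dr",
    "scap_winging",
    "trunk_fw_flexion",
    "trunk_ax_rotation",
    "trunk_lat_flexion",
)

#: Scapular degrees of freedom (subset of KIN_CHANNELS).
SCAP_DOFS = ("scap_ab_ad", "scap_el_dep", "scap_ur_dr", "scap_winging")

#: Trunk degrees of freedom used for compensation metrics.
TRUNK_DOFS = ("trunk_fw_flexion", "trunk_ax_rotation", "trunk_lat_flexion")

#: Muscles with surface EMG, using the field's usual abbreviations.
MUSCLES = ("UT", "MT", "LT", "SAupmid", "SAlow", "LS")


class ScapkinError(Exception):
    """Base class for all package errors."""


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled channel.

    Parameters
    ----------
    samples : ndarray
        Sample values; must be finite.
    rate : float
        Sampling rate in Hz, > 0.
    units : str
        Physical units, e.g. ``"deg"``, ``"m/s^2"``, ``"%SVIC"``.
    label : str
        Channel name.
    """

    samples: np.ndarray
    rate: float
    units: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise ScapkinError(f"rate must be > 0, got {self.rate}")
        if samples.ndim != 1:
            raise ScapkinError("TimeSeries samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ScapkinError(f"non-finite samples in channel {self.label!r}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Recording span in seconds (n / rate)."""
        return self.n / self.rate

    def time(self) -> np.ndarray:
        """Time stamps in seconds, 0-based at the first sample."""
        return np.arange(self.n) / self.rate

    def index_at(self, t: float) -> int:
        """Nearest sample index for time ``t`` (clipped to the record)."""
        return int(np.clip(round(t * self.rate), 0, self.n - 1))

    def crop(self, t0: float, t1: float) -> "TimeSeries":
        """Inclusive window [t0, t1] as a new series."""
        i0, i1 = self.index_at(t0), self.index_at(t1)
        if i1 < i0:
            raise ScapkinError(f"empty window [{t0}, {t1}] on {self.label!r}")
        return replace(self, samples=self.samples[i0 : i1 + 1])

    def with_samples(self, samples: np.ndarray) -> "TimeSeries":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class SvicRecording:
    """Three 5-s submaximal isometric repetitions for one muscle."""

    muscle: str
    repetitions: tuple[TimeSeries, ...]

    def __post_init__(self) -> None:
        if len(self.repetitions) != 3:
            raise ScapkinError(
                f"SVIC for {self.muscle} needs exactly 3 repetitions, "
                f"got {len(self.repetitions)}"
            )


@dataclass
class TrialRecording:
    """Synchronised channels for one execution of the drinking task.

    ``kin`` holds the angle channels on the kinematic time base, ``hf`` the
    high-frequency block (hand acceleration plus the six EMG channels).  EMG
    may be stored either as an amplitude envelope (``emg_mode="envelope"``)
    or as a raw interference-pattern signal (``emg_mode="raw"``) that still
    needs the band-pass + RMS chain.  Both blocks start at the same instant;
    a pre-task rest segment of ``rest_duration`` seconds precedes movement.
    """

    kin: pd.DataFrame
    hf: pd.DataFrame
    kin_rate: float
    hf_rate: float
    rest_duration: float
    emg_mode: str = "envelope"
    subject: str = "S01"
    session: str = "M0"
    trial: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in KIN_CHANNELS if c not in self.kin.columns]
        if missing:
            raise ScapkinError(f"missing kinematic channel(s): {missing}")
        if "hand_accel" not in self.hf.columns:
            raise ScapkinError("missing channel 'hand_accel'")
        for m in MUSCLES:
            if f"emg_{m}" not in self.hf.columns:
                raise ScapkinError(f"missing channel 'emg_{m}'")
        if self.emg_mode not in ("envelope", "raw"):
            raise ScapkinError(f"unknown emg_mode {self.emg_mode!r}")
        if self.rest_duration < 5.0:
            raise ScapkinError("rest segment must cover at least 5 s")

    def angle(self, name: str) -> TimeSeries:
        return TimeSeries(self.kin[name].to_numpy(), self.kin_rate, "deg", name)

    def accel(self) -> TimeSeries:
        return TimeSeries(
            self.hf["hand_accel"].to_numpy(), self.hf_rate, "m/s^2", "hand_accel"
        )

    def emg(self, muscle: str) -> TimeSeries:
        units = "V" if self.emg_mode == "raw" else "envelope"
        return TimeSeries(
            self.hf[f"emg_{muscle}"].to_numpy(), self.hf_rate, units, f"emg_{muscle}"
        )

    @property
    def duration(self) -> float:
        return len(self.kin) / self.kin_rate


@dataclass(frozen=True)
class PhaseSegmentation:
    """Task onset, the four interior phase boundaries and the task end (s)."""

    onset: float
    b1: float
    b2: float
    b3: float
    b4: float
    end: float

    def __post_init__(self) -> None:
        ts = self.as_tuple()
        if not all(a < b for a, b in zip(ts, ts[1:])):
            raise ScapkinError(f"boundaries must be strictly increasing: {ts}")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.onset, self.b1, self.b2, self.b3, self.b4, self.end)

    def phase_window(self, phase: str) -> tuple[float, float]:
        """Inclusive [start, end] time window of a named phase."""
        edges = self.as_tuple()
        i = PHASES.index(phase)
        return edges[i], edges[i + 1]

    def shifted(self, dt: float) -> "PhaseSegmentation":
        return PhaseSegmentation(*(t + dt for t in self.as_tuple()))
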