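"""Plain-text file formats and the run configuration.

Trials are stored as tab-separated files with a typed ``#``-prefixed header
and one block per time base (kinematics at 100 Hz, the high-frequency
acceleration/EMG block at 2000 Hz).  Times are serialised in seconds from
the start of the recording (0-based); angles in degrees with the sign
conventions stated in the header.  The commercial motion platform's binary
format is proprietary; C3D import is a documented extension point, not
implemented.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import ProcessingParams
from .core import MUSCLES, ScapkinError, SvicRecording, TimeSeries, TrialRecording
from .segmentation import SegmentationParams
from .synthetic import EffectSpec, GeneratorConfig

_SIGNS = ("scap Ab(+)/Ad(-), El(+)/Dep(-), Ur(+)/Dr(-), Wing(+); "
          "trunk FwFlex(-)/Ext(+), AxRot/LatFlex (+) toward assessed side; "
          "elbow extension (+)")


def _header_lines(pairs: dict) -> list[str]:
    return [f"# {k}: {v}" for k, v in pairs.items()]


def write_trial(trial: TrialRecording, path: str | Path) -> None:
    """Serialise one trial; full float precision, deterministic bytes."""
    path = Path(path)
    lines = ["# scapkin-trial v1"]
    lines += _header_lines({
        "subject": trial.subject, "session": trial.session,
        "trial": trial.trial, "rest_duration_s": trial.rest_duration,
        "emg_mode": trial.emg_mode, "signs": _SIGNS,
    })
    out = []
    for name, frame, rate in (("kin", trial.kin, trial.kin_rate),
                              ("hf", trial.hf, trial.hf_rate)):
        block = frame.copy()
        block.insert(0, "time_s", np.arange(len(block)) / rate)
        buf = _io.StringIO()
        block.to_csv(buf, sep="\t", index=False, float_format="%.17g")
        out.append(f"# block: {name} rate_hz={rate} n={len(block)}\n" + buf.getvalue())
    path.write_text("\n".join(lines) + "\n" + "".join(out))


def _parse_trial_text(text: str):
    header: dict[str, str] = {}
    blocks: dict[str, tuple[float, int, pd.DataFrame]] = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("# block:"):
            spec = line[len("# block:"):].split()
            name = spec[0]
            attrs = dict(kv.split("=") for kv in spec[1:])
            j = i + 1
            while j < len(lines) and not lines[j].startswith("#"):
                j += 1
            frame = pd.read_csv(_io.StringIO("\n".join(lines[i + 1 : j])),
                                sep="\t", float_precision="round_trip")
            blocks[name] = (float(attrs["rate_hz"]), int(attrs["n"]), frame)
            i = j
            continue
        if line.startswith("#") and ":" in line:
            key, _, value = line[1:].partition(":")
            header[key.strip()] = value.strip()
        i += 1
    return header, blocks


def read_trial(path: str | Path) -> TrialRecording:
    """Parse and validate a trial file (inverse of :func:`write_trial`)."""
    text = Path(path).read_text()
    header, blocks = _parse_trial_text(text)
    for name in ("kin", "hf"):
        if name not in blocks:
            raise ScapkinError(f"trial file missing block {name!r}")
        rate, n_declared, frame = blocks[name]
        if len(frame) != n_declared:
            raise ScapkinError(
                f"block {name}: {len(frame)} rows but header declares {n_declared}")
        t = frame["time_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ScapkinError(f"block {name}: non-monotone time column")
        expected = np.arange(len(t)) / rate
        if np.max(np.abs(t - expected)) > 0.5 / rate:
            raise ScapkinError(
                f"block {name}: time column inconsistent with declared rate {rate} Hz")
    kin_rate, _, kin = blocks["kin"]
    hf_rate, _, hf = blocks["hf"]
    span_kin, span_hf = len(kin) / kin_rate, len(hf) / hf_rate
    if abs(span_kin - span_hf) > 1.0 / kin_rate:
        raise ScapkinError(
            f"blocks cover different spans: {span_kin:.3f}s vs {span_hf:.3f}s")
    return TrialRecording(
        kin=kin.drop(columns="time_s"), hf=hf.drop(columns="time_s"),
        kin_rate=kin_rate, hf_rate=hf_rate,
        rest_duration=float(header["rest_duration_s"]),
        emg_mode=header.get("emg_mode", "envelope"),
        subject=header.get("subject", "S01"),
        session=header.get("session", "M0"),
        trial=int(header.get("trial", 1)),
    )


def write_svic_set(svic_set: dict[str, SvicRecording], path: str | Path,
                   subject: str = "S01") -> None:
    """Serialise a subject's SVIC recordings as one long tab-separated file."""
    rate = svic_set[next(iter(svic_set))].repetitions[0].rate
    mode = ("raw" if svic_set[next(iter(svic_set))].repetitions[0].units == "V"
            else "envelope")
    frames = []
    for muscle, rec in svic_set.items():
        for r, rep in enumerate(rec.repetitions, start=1):
            frames.append(pd.DataFrame(
                {"muscle": muscle, "rep": r, "value": rep.samples}))
    long = pd.concat(frames, ignore_index=True)
    buf = _io.StringIO()
    long.to_csv(buf, sep="\t", index=False, float_format="%.17g")
    head = "\n".join(["# scapkin-svic v1"] + _header_lines(
        {"subject": subject, "rate_hz": rate, "emg_mode": mode}))
    Path(path).write_text(head + "\n" + buf.getvalue())


def read_svic_set(path: str | Path) -> dict[str, SvicRecording]:
    text = Path(path).read_text()
    header_lines = [l for l in text.splitlines() if l.startswith("#")]
    header = {}
    for line in header_lines:
        if ":" in line:
            k, _, v = line[1:].partition(":")
            header[k.strip()] = v.strip()
    body = "\n".join(l for l in text.splitlines() if not l.startswith("#"))
    long = pd.read_csv(_io.StringIO(body), sep="\t",
                       float_precision="round_trip")
    rate = float(header["rate_hz"])
    units = "V" if header.get("emg_mode") == "raw" else "envelope"
    out = {}
    for muscle, grp in long.groupby("muscle", sort=False):
        reps = tuple(
            TimeSeries(sub["value"].to_numpy(), rate, units,
                       f"svic_{muscle}_rep{r}")
            for r, sub in grp.groupby("rep", sort=True)
        )
        out[str(muscle)] = SvicRecording(muscle=str(muscle), repetitions=reps)
    return out


# --------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """Everything a full study run needs; round-trips losslessly via YAML."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    processing: ProcessingParams = field(default_factory=ProcessingParams)
    sd_source: str = "first"          # SD entering the SEM
    adjust: str = "none"              # multiple-comparison adjustment
    tails: str = "one"                # power-analysis default
    aggregate_fallback: str = "error"
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.sd_source not in ("first", "pooled"):
            raise ScapkinError(f"unknown sd_source {self.sd_source!r}")
        if self.adjust not in ("none", "holm"):
            raise ScapkinError(f"unknown adjustment {self.adjust!r}")


def _effect_to_dict(eff: EffectSpec) -> dict:
    return {
        "rom": [{"channel": c, "phase": p, "delta": d}
                for (c, p), d in eff.rom.items()],
        "emg": [{"muscle": m, "phase": p, "delta": d}
                for (m, p), d in eff.emg.items()],
        "rest": dict(eff.rest),
        "smoothness_count": eff.smoothness_count,
        "smoothness_amp": eff.smoothness_amp,
    }


def _effect_from_dict(d: dict) -> EffectSpec:
    return EffectSpec(
        rom={(e["channel"], e["phase"]): e["delta"] for e in d.get("rom", [])},
        emg={(e["muscle"], e["phase"]): e["delta"] for e in d.get("emg", [])},
        rest=dict(d.get("rest", {})),
        smoothness_count=int(d.get("smoothness_count", 0)),
        smoothness_amp=float(d.get("smoothness_amp", 0.0)),
    )


def config_to_dict(config: RunConfig) -> dict:
    gen = asdict(config.generator)
    gen["phase_durations"] = list(config.generator.phase_durations)
    gen["elbow_deltas"] = list(config.generator.elbow_deltas)
    gen["hand_deltas"] = list(config.generator.hand_deltas)
    gen["smoothness_perturbation"] = list(config.generator.smoothness_perturbation)
    gen["rom_true"] = {k: list(v) for k, v in config.generator.rom_true.items()}
    gen["emg_level_true"] = {k: list(v)
                             for k, v in config.generator.emg_level_true.items()}
    gen["effect_delta"] = _effect_to_dict(config.generator.effect_delta)
    proc = asdict(config.processing)
    return {
        "generator": gen, "processing": proc, "sd_source": config.sd_source,
        "adjust": config.adjust, "tails": config.tails,
        "aggregate_fallback": config.aggregate_fallback,
        "out_dir": config.out_dir,
    }


def config_from_dict(data: dict) -> RunConfig:
    gen = dict(data.get("generator", {}))
    for key in ("phase_durations", "elbow_deltas", "hand_deltas",
                "smoothness_perturbation"):
        if key in gen:
            gen[key] = tuple(gen[key])
    for key in ("rom_true", "emg_level_true"):
        if key in gen:
            gen[key] = {k: tuple(v) for k, v in gen[key].items()}
    if "effect_delta" in gen:
        gen["effect_delta"] = _effect_from_dict(gen["effect_delta"])
    proc = dict(data.get("processing", {}))
    if "segmentation" in proc:
        proc["segmentation"] = SegmentationParams(**proc["segmentation"])
    return RunConfig(
        generator=GeneratorConfig(**gen),
        processing=ProcessingParams(**proc),
        sd_source=data.get("sd_source", "first"),
        adjust=data.get("adjust", "none"),
        tails=data.get("tails", "one"),
        aggregate_fallback=data.get("aggregate_fallback", "error"),
        out_dir=data.get("out_dir", "results"),
    )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
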