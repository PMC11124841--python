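"""Synthetic labeled multi-sensor recordings for end-to-end testing.

The generators emulate the structure of public wearable-sensor corpora:
tri-axial inertial channels at 32 Hz, GPS fixes at 1 Hz, and mono audio clips,
each recording carrying a physical-activity and/or localization label. Class
signatures are chosen so that the pipeline's feature set — gait frequency,
per-channel variance and shape statistics, step counts, trajectory speed, and
audio spectral shape — separates them, not the raw samples themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import json

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core_io import SensorRecording, read_recording, write_audio
from .errors import ParameterError

START_LAT, START_LON = 47.0, 8.0  # arbitrary mid-latitude origin


@dataclass(frozen=True)
class ClassSpec:
    """One synthetic class: name, stream, and generator parameters."""

    name: str
    stream: str  # "physical" | "localization"
    count: int = 10
    inertial: str | Mapping | None = None  # defaults to the preset for `name`
    gps: str | Mapping | None = None
    audio: str | None = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ParameterError("class count must be >= 1")
        if self.stream not in ("physical", "localization"):
            raise ParameterError(f"unknown stream {self.stream!r}")


@dataclass(frozen=True)
class SynthSpec:
    classes: tuple[ClassSpec, ...]
    duration_s: float = 30.0
    inertial_rate_hz: float = 32.0
    gps_rate_hz: float = 1.0
    audio_rate_hz: float = 4000.0
    noise_sd: float = 0.05
    gps_jitter_m: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inertial_rate_hz <= 0 or self.gps_rate_hz <= 0 or self.audio_rate_hz <= 0:
            raise ParameterError("sample rates must be > 0")


#: per-class inertial signatures: gait frequency (Hz), acceleration amplitude,
#: gyro scale, magnetometer mean orientation (unit-ish vector) and spread
INERTIAL_PRESETS: dict[str, dict] = {
    "sit": dict(freq=0.0, amp=0.0, gyro_sd=0.02, mag_mean=(20.0, 5.0, -40.0), mag_sd=0.3, drift=0.0),
    "stand": dict(freq=0.05, amp=0.25, gyro_sd=0.06, mag_mean=(5.0, 20.0, -40.0), mag_sd=0.3, drift=0.3),
    "walk": dict(freq=2.0, amp=1.0, gyro_sd=0.5, mag_mean=(15.0, 15.0, -40.0), mag_sd=1.0, drift=0.0),
    "run": dict(freq=3.0, amp=2.5, gyro_sd=1.0, mag_mean=(-10.0, 20.0, -40.0), mag_sd=2.0, drift=0.0),
}

GPS_PRESETS: dict[str, dict] = {
    "stationary": dict(speed=0.0, turn_deg_s=0.0),
    "pedestrian": dict(speed=1.4, turn_deg_s=2.0),
    "vehicle": dict(speed=15.0, turn_deg_s=6.0),
}

LOCALIZATION_PRESETS: dict[str, dict] = {
    "indoor": dict(inertial=dict(freq=1.8, amp=0.8, gyro_sd=0.4, mag_mean=(25.0, 5.0, -40.0), mag_sd=0.5, drift=0.0), gps="stationary", audio="indoor"),
    "outdoor": dict(inertial=dict(freq=2.0, amp=1.2, gyro_sd=0.6, mag_mean=(10.0, 20.0, -40.0), mag_sd=1.5, drift=0.0), gps="pedestrian", audio="outdoor"),
    "vehicle": dict(inertial=dict(freq=8.0, amp=0.3, gyro_sd=0.1, mag_mean=(-20.0, 10.0, -40.0), mag_sd=0.8, drift=0.0), gps="vehicle", audio="vehicle"),
}

GRAVITY = 9.81


def gen_inertial(
    class_name: str | Mapping,
    spec: SynthSpec,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Nine inertial channels with a class-specific signature.

    Sitting is low-variance noise about the gravity vector; standing adds a
    slow postural drift; walking and running are periodic at their gait
    frequencies with increasing amplitude.
    """
    if isinstance(class_name, Mapping):
        params = dict(class_name)
    elif class_name in INERTIAL_PRESETS:
        params = dict(INERTIAL_PRESETS[class_name])
    else:
        raise ParameterError(f"unknown inertial class {class_name!r} and no parameters given")
    n = int(round(spec.duration_s * spec.inertial_rate_hz))
    t = np.arange(n) / spec.inertial_rate_hz
    freq, amp = params["freq"], params["amp"]
    phases = rng.uniform(0, 2 * np.pi, size=3)
    axis_w = np.array([0.6, 0.3, 1.0])  # gait mostly vertical

    channels: dict[str, np.ndarray] = {}
    for i, ax in enumerate(("acc_x", "acc_y", "acc_z")):
        base = GRAVITY if ax == "acc_z" else 0.0
        periodic = amp * axis_w[i] * np.sin(2 * np.pi * freq * t + phases[i]) if freq > 0 else 0.0
        drift = params.get("drift", 0.0) * np.sin(2 * np.pi * 0.05 * t + phases[i])
        channels[ax] = base + periodic + drift + rng.normal(0, spec.noise_sd, n)
    for i, ax in enumerate(("gyr_x", "gyr_y", "gyr_z")):
        periodic = (
            0.5 * params["gyro_sd"] * np.sin(2 * np.pi * freq * t + phases[i] + 1.0)
            if freq > 0
            else 0.0
        )
        channels[ax] = periodic + rng.normal(0, params["gyro_sd"] + spec.noise_sd, n)
    for i, ax in enumerate(("mag_x", "mag_y", "mag_z")):
        channels[ax] = params["mag_mean"][i] + rng.normal(
            0, params["mag_sd"] + spec.noise_sd, n
        )
    return channels


def gen_gps(
    mode: str | Mapping,
    spec: SynthSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """(t, lat, lon) track: straight or gently turning motion plus fix jitter."""
    if isinstance(mode, Mapping):
        params = dict(mode)
    elif mode in GPS_PRESETS:
        params = dict(GPS_PRESETS[mode])
    else:
        raise ParameterError(f"unknown GPS mode {mode!r} and no parameters given")
    speed = params["speed"]
    if speed < 0:
        raise ParameterError("GPS speed must be >= 0")
    n = max(2, int(round(spec.duration_s * spec.gps_rate_hz)))
    dt = 1.0 / spec.gps_rate_hz
    heading = rng.uniform(0, 360.0)
    lat, lon = START_LAT, START_LON
    deg_per_m_lat = 180.0 / (np.pi * 6_371_000.0)
    rows = []
    for i in range(n):
        jitter = rng.normal(0, spec.gps_jitter_m, 2)
        rows.append(
            (
                i * dt,
                lat + jitter[0] * deg_per_m_lat,
                lon + jitter[1] * deg_per_m_lat / np.cos(np.radians(lat)),
            )
        )
        step = speed * dt
        lat += step * np.cos(np.radians(heading)) * deg_per_m_lat
        lon += step * np.sin(np.radians(heading)) * deg_per_m_lat / np.cos(np.radians(lat))
        heading += params.get("turn_deg_s", 0.0) * dt
    return np.asarray(rows)


def gen_audio(
    environment: str,
    spec: SynthSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mono audio clip with an environment-specific spectral signature.

    Indoor clips are narrowband low-frequency tones over pink-ish noise;
    outdoor clips are broadband noise with a higher spectral centroid; vehicle
    clips add a strong engine-like hum.
    """
    n = int(round(spec.duration_s * spec.audio_rate_hz))
    if n == 0:
        raise ParameterError("zero-duration audio requested")
    t = np.arange(n) / spec.audio_rate_hz
    white = rng.normal(0, 1.0, n)
    # one-pole lowpass turns white noise pink-ish (energy concentrated at low f)
    pink = lfilter([0.1], [1.0, -0.97], white)
    if environment == "indoor":
        clip = 0.6 * np.sin(2 * np.pi * 150 * t) + 0.4 * np.sin(2 * np.pi * 320 * t) + 0.5 * pink
    elif environment == "outdoor":
        clip = 0.9 * white + 0.1 * pink
    elif environment == "vehicle":
        clip = 0.8 * np.sin(2 * np.pi * 80 * t) + 0.3 * np.sin(2 * np.pi * 160 * t) + 0.3 * white
    else:
        raise ParameterError(f"unknown audio environment {environment!r}")
    peak = np.max(np.abs(clip))
    return clip / peak if peak > 0 else clip


def _resolve_class(cls: ClassSpec) -> ClassSpec:
    """Fill in generator presets when only a class name is given."""
    if cls.inertial is None:
        if cls.stream == "localization" and cls.name in LOCALIZATION_PRESETS:
            preset = LOCALIZATION_PRESETS[cls.name]
            return replace(
                cls,
                inertial=preset["inertial"],
                gps=cls.gps if cls.gps is not None else preset["gps"],
                audio=cls.audio if cls.audio is not None else preset["audio"],
            )
        if cls.name in INERTIAL_PRESETS:
            return replace(cls, inertial=cls.name)
        raise ParameterError(
            f"unknown class {cls.name!r} and no generator parameters given"
        )
    return cls


def gen_recording(
    cls: ClassSpec, spec: SynthSpec, rng: np.random.Generator, recording_id: str
) -> SensorRecording:
    cls = _resolve_class(cls)
    channels = gen_inertial(cls.inertial, spec, rng)
    gps = gen_gps(cls.gps, spec, rng) if cls.gps is not None else np.empty((0, 3))
    audio = gen_audio(cls.audio, spec, rng) if cls.audio is not None else None
    return SensorRecording(
        recording_id=recording_id,
        channels=channels,
        sample_rate_hz=spec.inertial_rate_hz,
        gps_track=gps,
        audio=audio,
        audio_sample_rate_hz=spec.audio_rate_hz if audio is not None else None,
        physical_label=cls.name if cls.stream == "physical" else None,
        localization_label=cls.name if cls.stream == "localization" else None,
    )


def gen_dataset(spec: SynthSpec) -> list[SensorRecording]:
    """Labeled recording collection honoring per-class counts; all randomness
    derives from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    recordings = []
    for cls in spec.classes:
        for i in range(cls.count):
            recordings.append(
                gen_recording(cls, spec, rng, recording_id=f"{cls.name}_{i:03d}")
            )
    return recordings


def imbalanced_counts(majority: int, ratio: float, n_classes: int) -> list[int]:
    """Counts [majority, majority/ratio, ...] for an imbalance experiment."""
    if ratio < 1:
        raise ParameterError("imbalance ratio must be >= 1")
    return [majority] + [max(1, int(round(majority / ratio)))] * (n_classes - 1)


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------


def write_dataset(recordings: Sequence[SensorRecording], out_dir: str | Path) -> Path:
    """Write the documented CSV/WAV layout plus a labels manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for rec in recordings:
        n = rec.n_samples
        df = pd.DataFrame({"timestamp": np.arange(n) / rec.sample_rate_hz})
        for name, x in rec.channels.items():
            df[name] = x
        inertial = f"{rec.recording_id}_inertial.csv"
        df.to_csv(out_dir / inertial, index=False, float_format="%.9g")
        entry = {
            "recording_id": rec.recording_id,
            "inertial": inertial,
            "gps": None,
            "audio": None,
            "physical_label": rec.physical_label,
            "localization_label": rec.localization_label,
        }
        if len(rec.gps_track):
            gps_name = f"{rec.recording_id}_gps.csv"
            pd.DataFrame(
                rec.gps_track, columns=["timestamp", "latitude", "longitude"]
            ).to_csv(out_dir / gps_name, index=False, float_format="%.12g")
            entry["gps"] = gps_name
        if rec.audio is not None:
            wav_name = f"{rec.recording_id}_audio.wav"
            write_audio(rec.audio, rec.audio_sample_rate_hz, out_dir / wav_name)
            entry["audio"] = wav_name
        manifest.append(entry)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out_dir


def read_dataset(in_dir: str | Path) -> list[SensorRecording]:
    """Read a dataset directory written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    recordings = []
    for entry in manifest:
        labels = {}
        if entry.get("physical_label"):
            labels["physical"] = entry["physical_label"]
        if entry.get("localization_label"):
            labels["localization"] = entry["localization_label"]
        recordings.append(
            read_recording(
                in_dir / entry["inertial"],
                gps_path=in_dir / entry["gps"] if entry.get("gps") else None,
                audio_path=in_dir / entry["audio"] if entry.get("audio") else None,
                labels=labels,
                recording_id=entry["recording_id"],
            )
        )
    return recordings
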