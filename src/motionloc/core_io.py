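"""Domain types and file I/O for sensor logs, feature matrices and metrics.

The on-disk conventions are deliberately plain text:

* inertial logs — CSV with a ``timestamp`` column (seconds) plus any subset of
  the nine canonical channel columns (``acc_x`` … ``mag_z``);
* GPS tracks — CSV with ``timestamp, latitude, longitude``;
* audio — mono PCM WAV;
* feature matrices — CSV with ``row_id``, ``label``, ``augmented`` and one
  column per feature;
* metrics reports — JSON with a deterministic field order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import ParseError, SchemaError, ValidationError

log = logging.getLogger(__name__)

#: canonical inertial channel names, grouped by sensor
CHANNEL_GROUPS: dict[str, tuple[str, ...]] = {
    "acc": ("acc_x", "acc_y", "acc_z"),
    "gyr": ("gyr_x", "gyr_y", "gyr_z"),
    "mag": ("mag_x", "mag_y", "mag_z"),
}
INERTIAL_CHANNELS: tuple[str, ...] = tuple(
    ch for group in CHANNEL_GROUPS.values() for ch in group
)

#: declared-vs-inferred sample-rate agreement required by read_recording
RATE_TOLERANCE = 0.20


@dataclass
class SensorRecording:
    """One labeled multi-channel recording (inertial + optional GPS/audio)."""

    recording_id: str
    channels: dict[str, np.ndarray]
    sample_rate_hz: float
    gps_track: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), dtype=float)
    )
    audio: np.ndarray | None = None
    audio_sample_rate_hz: float | None = None
    physical_label: str | None = None
    localization_label: str | None = None

    def __post_init__(self) -> None:
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        self.gps_track = np.asarray(self.gps_track, dtype=float).reshape(-1, 3)
        if self.audio is not None:
            self.audio = np.asarray(self.audio, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ValidationError(f"{self.recording_id}: sample rate must be > 0")
        if self.audio is not None and (
            self.audio_sample_rate_hz is None or self.audio_sample_rate_hz <= 0
        ):
            raise ValidationError(f"{self.recording_id}: audio requires a positive rate")
        for group, names in CHANNEL_GROUPS.items():
            lengths = {len(self.channels[ch]) for ch in names if ch in self.channels}
            if len(lengths) > 1:
                raise ValidationError(
                    f"{self.recording_id}: {group} channels have unequal lengths {lengths}"
                )
        if len(self.gps_track):
            t, lat, lon = self.gps_track.T
            if np.any(np.diff(t) <= 0):
                raise ValidationError(
                    f"{self.recording_id}: GPS timestamps not strictly increasing"
                )
            if np.any(np.abs(lat) > 90.0):
                raise ValidationError(f"{self.recording_id}: latitude out of [-90, 90]")
            if np.any(np.abs(lon) > 180.0):
                raise ValidationError(f"{self.recording_id}: longitude out of [-180, 180]")

    @property
    def n_samples(self) -> int:
        return max((len(v) for v in self.channels.values()), default=0)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass
class SignalWindow:
    """A fixed-duration segment of one recording with an inherited label."""

    source_id: str
    channels: dict[str, np.ndarray]
    start_time: float
    duration: float
    sample_rate_hz: float
    label: str | None = None
    augmented: bool = False
    gps_track: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), dtype=float)
    )
    audio: np.ndarray | None = None
    audio_sample_rate_hz: float | None = None

    def __post_init__(self) -> None:
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValidationError(f"{self.source_id}: window channels differ in length")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0

    @property
    def window_id(self) -> str:
        tag = "|aug" if self.augmented else ""
        return f"{self.source_id}@{self.start_time:.3f}{tag}"

    def copy(self, **changes) -> "SignalWindow":
        new = replace(self, **changes)
        new.channels = {k: v.copy() for k, v in new.channels.items()}
        return new


@dataclass
class FeatureMatrix:
    """Windows-by-features matrix with labels and augmentation provenance."""

    feature_names: list[str]
    rows: np.ndarray
    labels: list[str]
    augmented_flags: np.ndarray
    row_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float).reshape(-1, len(self.feature_names))
        self.labels = list(self.labels)
        self.augmented_flags = np.asarray(self.augmented_flags, dtype=bool)
        if self.rows.shape[0] != len(self.labels) or self.rows.shape[0] != len(
            self.augmented_flags
        ):
            raise ValidationError("feature matrix rows/labels/flags length mismatch")
        if self.row_ids is not None and len(self.row_ids) != self.rows.shape[0]:
            raise ValidationError("row_ids length mismatch")
        if self.rows.size and not np.all(np.isfinite(self.rows)):
            bad = np.argwhere(~np.isfinite(self.rows))[0]
            raise ValidationError(
                f"non-finite feature value at row {bad[0]}, "
                f"column {self.feature_names[bad[1]]}"
            )

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    def column(self, name: str) -> np.ndarray:
        try:
            return self.rows[:, self.feature_names.index(name)]
        except ValueError:
            raise SchemaError(f"unknown feature {name!r}") from None

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = []
        for name in names:
            if name not in self.feature_names:
                raise SchemaError(f"unknown feature {name!r}")
            idx.append(self.feature_names.index(name))
        return FeatureMatrix(
            list(names), self.rows[:, idx], self.labels, self.augmented_flags, self.row_ids
        )


@dataclass
class MetricsReport:
    """Row-normalized confusion matrix plus per-class P/R/F1 and AUC."""

    class_names: list[str]
    confusion: np.ndarray
    mean_accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    auc: dict[str, float]
    macro_auc: float = float("nan")
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=float)
        k = len(self.class_names)
        if self.confusion.shape != (k, k):
            raise ValidationError(
                f"confusion matrix shape {self.confusion.shape} not ({k}, {k})"
            )
        sums = self.confusion.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValidationError("confusion rows must sum to 1")
        if abs(self.mean_accuracy - float(np.mean(np.diag(self.confusion)))) > 1e-9:
            raise ValidationError("mean_accuracy must equal the mean of the diagonal")

    def to_dict(self) -> dict:
        return {
            "class_names": self.class_names,
            "confusion": [[float(v) for v in row] for row in self.confusion],
            "mean_accuracy": float(self.mean_accuracy),
            "precision": {c: float(self.precision[c]) for c in self.class_names},
            "recall": {c: float(self.recall[c]) for c in self.class_names},
            "f1": {c: float(self.f1[c]) for c in self.class_names},
            "auc": {c: float(self.auc[c]) for c in self.class_names},
            "macro_auc": float(self.macro_auc),
            "n_samples": int(self.n_samples),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MetricsReport":
        return cls(
            class_names=list(d["class_names"]),
            confusion=np.asarray(d["confusion"], dtype=float),
            mean_accuracy=float(d["mean_accuracy"]),
            precision=dict(d["precision"]),
            recall=dict(d["recall"]),
            f1=dict(d["f1"]),
            auc=dict(d["auc"]),
            macro_auc=float(d.get("macro_auc", float("nan"))),
            n_samples=int(d.get("n_samples", 0)),
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_numeric_csv(path: Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(required))
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2 accounts for the header row and 1-based line numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ParseError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = coerced
    if df.isna().any().any():
        line = int(np.flatnonzero(df.isna().any(axis=1).to_numpy())[0]) + 2
        raise ParseError(f"{path}: missing value at line {line}")
    return df


def infer_sample_rate(timestamps: np.ndarray) -> float:
    """Sample rate as 1 / median timestamp spacing."""
    dt = np.diff(np.asarray(timestamps, dtype=float))
    if len(dt) == 0:
        raise ValidationError("cannot infer sample rate from fewer than 2 samples")
    if np.any(dt <= 0):
        raise ValidationError("timestamps not strictly increasing")
    return 1.0 / float(np.median(dt))


def read_recording(
    inertial_path: str | Path,
    gps_path: str | Path | None = None,
    audio_path: str | Path | None = None,
    labels: Mapping[str, str] | None = None,
    recording_id: str | None = None,
    declared_rate_hz: float | None = None,
) -> SensorRecording:
    """Read a recording from the documented CSV/WAV layout and validate it."""
    inertial_path = Path(inertial_path)
    df = _read_numeric_csv(inertial_path, required=["timestamp"])
    timestamps = df["timestamp"].to_numpy(dtype=float)
    rate = infer_sample_rate(timestamps)
    if declared_rate_hz is not None:
        if abs(rate - declared_rate_hz) > RATE_TOLERANCE * declared_rate_hz:
            raise ValidationError(
                f"{inertial_path}: inferred rate {rate:.2f} Hz disagrees with "
                f"declared {declared_rate_hz} Hz by more than {RATE_TOLERANCE:.0%}"
            )
        rate = float(declared_rate_hz)

    channels: dict[str, np.ndarray] = {}
    for col in df.columns:
        if col == "timestamp":
            continue
        if col in INERTIAL_CHANNELS:
            channels[col] = df[col].to_numpy(dtype=float)
        else:
            log.warning("%s: ignoring unknown column %r", inertial_path, col)
    if not channels:
        raise SchemaError(f"{inertial_path}: no known channel columns found")

    gps = np.empty((0, 3), dtype=float)
    if gps_path is not None:
        gdf = _read_numeric_csv(Path(gps_path), required=[])
        if len(gdf):
            for col in ("timestamp", "latitude", "longitude"):
                if col not in gdf.columns:
                    raise SchemaError(f"{gps_path}: missing required column {col!r}")
            gps = gdf[["timestamp", "latitude", "longitude"]].to_numpy(dtype=float)

    audio = None
    audio_rate = None
    if audio_path is not None:
        sr, data = wavfile.read(audio_path)
        if data.ndim != 1:
            raise SchemaError(f"{audio_path}: audio must be mono")
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(float) / float(np.iinfo(data.dtype).max)
        audio = np.asarray(data, dtype=float)
        audio_rate = float(sr)

    labels = labels or {}
    return SensorRecording(
        recording_id=recording_id or inertial_path.stem,
        channels=channels,
        sample_rate_hz=rate,
        gps_track=gps,
        audio=audio,
        audio_sample_rate_hz=audio_rate,
        physical_label=labels.get("physical"),
        localization_label=labels.get("localization"),
    )


def write_audio(audio: np.ndarray, sample_rate_hz: float, path: str | Path) -> None:
    """Write a mono float signal as 16-bit PCM WAV."""
    scaled = np.asarray(audio, dtype=float)
    peak = float(np.max(np.abs(scaled))) if scaled.size else 0.0
    if peak > 1.0:
        scaled = scaled / peak
    wavfile.write(str(path), int(round(sample_rate_hz)), (scaled * 32767).astype(np.int16))


_RESERVED_COLUMNS = ("row_id", "label", "augmented")


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    df = pd.DataFrame(fm.rows, columns=fm.feature_names)
    df.insert(0, "augmented", fm.augmented_flags.astype(int))
    df.insert(0, "label", fm.labels)
    df.insert(0, "row_id", fm.row_ids if fm.row_ids is not None else [""] * fm.n_rows)
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    for col in _RESERVED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    names = [c for c in df.columns if c not in _RESERVED_COLUMNS]
    row_ids = [str(v) for v in df["row_id"].fillna("")]
    return FeatureMatrix(
        feature_names=names,
        rows=df[names].to_numpy(dtype=float),
        labels=[str(v) for v in df["label"]],
        augmented_flags=df["augmented"].to_numpy(dtype=bool),
        row_ids=row_ids if any(row_ids) else None,
    )


def write_metrics_report(report: MetricsReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=False) + "\n")


def read_metrics_report(path: str | Path) -> MetricsReport:
    return MetricsReport.from_dict(json.loads(Path(path).read_text()))
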