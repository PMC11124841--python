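"""Denoising and windowed segmentation of sensor streams.

Inertial channels are denoised with a zero-phase low-pass Butterworth filter
(the "maximally flat magnitude" filter); GPS latitude/longitude sequences are
denoised with a small median filter, which is robust to the occasional wild
fix. Recordings are then cut into fixed-duration, optionally Hamming-tapered
windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal

from .core_io import INERTIAL_CHANNELS, SensorRecording, SignalWindow
from .errors import ParameterError, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter parameters."""

    order: int = 4
    cutoff_hz: float = 10.0
    sample_rate_hz: float = 32.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ParameterError("cutoff frequency must be > 0")
        if self.sample_rate_hz <= 0:
            raise ParameterError("sample rate must be > 0")
        if self.cutoff_hz >= self.sample_rate_hz / 2:
            raise ParameterError(
                f"cutoff {self.cutoff_hz} Hz must be below the Nyquist "
                f"frequency {self.sample_rate_hz / 2} Hz"
            )


def butterworth_gain(freq: float | np.ndarray, spec: FilterSpec) -> float | np.ndarray:
    """Magnitude response |H| = 1/sqrt(1 + (f/f_c)^(2n)) of an order-n filter.

    ``freq`` is in the same units as ``spec.cutoff_hz``; only the ratio enters.
    """
    f = np.asarray(freq, dtype=float)
    if np.any(f < 0):
        raise ParameterError("frequency must be >= 0")
    gain = 1.0 / np.sqrt(1.0 + (f / spec.cutoff_hz) ** (2 * spec.order))
    return float(gain) if np.isscalar(freq) else gain


def lowpass_filter(x: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Zero-phase (forward-backward) low-pass Butterworth filtering.

    Two passes square the magnitude response and cancel the phase, so the
    channels stay time-aligned.
    """
    x = np.asarray(x, dtype=float)
    padlen = 3 * (spec.order + 1)
    if len(x) < padlen:
        raise ParameterError(
            f"signal of length {len(x)} too short for order-{spec.order} "
            f"zero-phase filtering (need >= {padlen})"
        )
    b, a = signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=spec.sample_rate_hz)
    return signal.filtfilt(b, a, x, padlen=min(padlen, len(x) - 1))


def median_filter(x: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered running median with replicated endpoints."""
    x = np.asarray(x, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ParameterError("median filter window must be odd and positive")
    if window > len(x):
        raise ParameterError("median filter window exceeds signal length")
    return ndimage.median_filter(x, size=window, mode="nearest")


def hamming_window(n: int) -> np.ndarray:
    """W(k) = 0.54 - 0.46 cos(2*pi*k/(N-1)), k = 0..N-1."""
    if n < 2:
        raise ParameterError("Hamming window needs N >= 2")
    return np.hamming(n)


def denoise_recording(
    recording: SensorRecording,
    filter_spec: FilterSpec | None = None,
    median_window: int = 3,
) -> SensorRecording:
    """Butterworth-filter the inertial channels, median-filter lat/lon."""
    spec = filter_spec or FilterSpec(sample_rate_hz=recording.sample_rate_hz)
    if spec.sample_rate_hz != recording.sample_rate_hz:
        spec = replace(spec, sample_rate_hz=recording.sample_rate_hz)
    channels = {
        name: lowpass_filter(x, spec) if name in INERTIAL_CHANNELS else x.copy()
        for name, x in recording.channels.items()
    }
    gps = recording.gps_track.copy()
    if len(gps) >= median_window:
        gps[:, 1] = median_filter(gps[:, 1], median_window)
        gps[:, 2] = median_filter(gps[:, 2], median_window)
    return replace(recording, channels=channels, gps_track=gps)


def segment(
    recording: SensorRecording,
    window_s: float = 5.0,
    overlap_fraction: float = 0.5,
    apply_taper: bool = True,
    stream: str = "auto",
) -> list[SignalWindow]:
    """Cut a recording into fixed-length windows with the inherited label.

    The hop is N*(1-overlap); a trailing partial window is discarded. When
    ``apply_taper`` is set, each inertial channel is point-wise multiplied by
    the Hamming window. GPS fixes and audio samples falling inside the window's
    time span travel with it untouched (trajectory features need raw fixes and
    the MFCC pipeline tapers its own frames).
    """
    if not recording.channels:
        raise ValidationError(f"{recording.recording_id}: recording has no channels")
    if not 0 <= overlap_fraction < 1:
        raise ParameterError("overlap fraction must be in [0, 1)")
    if stream == "physical":
        label = recording.physical_label
    elif stream == "localization":
        label = recording.localization_label
    elif stream == "auto":
        label = (
            recording.physical_label
            if recording.physical_label is not None
            else recording.localization_label
        )
    else:
        raise ParameterError(f"unknown stream {stream!r}")

    rate = recording.sample_rate_hz
    n = int(round(window_s * rate))
    hop = max(1, int(round(n * (1 - overlap_fraction))))
    total = recording.n_samples
    if total < n:
        log.info(
            "%s: recording shorter than one window (%d < %d samples)",
            recording.recording_id,
            total,
            n,
        )
        return []

    taper = hamming_window(n) if apply_taper else None
    windows: list[SignalWindow] = []
    for start in range(0, total - n + 1, hop):
        t0 = start / rate
        chans = {}
        for name, x in recording.channels.items():
            seg = x[start : start + n].copy()
            if taper is not None and name in INERTIAL_CHANNELS:
                seg = seg * taper
            chans[name] = seg
        gps = recording.gps_track
        if len(gps):
            mask = (gps[:, 0] >= t0) & (gps[:, 0] < t0 + window_s)
            gps = gps[mask].copy()
        audio = None
        if recording.audio is not None:
            a0 = int(round(t0 * recording.audio_sample_rate_hz))
            a1 = int(round((t0 + window_s) * recording.audio_sample_rate_hz))
            audio = recording.audio[a0:a1].copy()
        windows.append(
            SignalWindow(
                source_id=recording.recording_id,
                channels=chans,
                start_time=t0,
                duration=window_s,
                sample_rate_hz=rate,
                label=label,
                gps_track=gps,
                audio=audio,
                audio_sample_rate_hz=recording.audio_sample_rate_hz,
            )
        )
    return windows
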