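"""Localization features: MFCCs from audio, step detection and heading from
inertial/magnetometer channels, trajectory statistics from GPS tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy import signal

from .core_io import SignalWindow
from .errors import ParameterError, SchemaError, UndefinedMetricError
from .features_motion import kurtosis, skewness

log = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0


# ---------------------------------------------------------------------------
# MFCC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MfccConfig:
    """MFCC pipeline parameters (speech-processing conventions)."""

    pre_emphasis: float = 0.97
    frame_s: float = 0.025
    hop_s: float = 0.010
    n_mel_filters: int = 26
    n_ceps: int = 13
    log_floor: float = 1e-10

    def __post_init__(self) -> None:
        if not 0 <= self.pre_emphasis < 1:
            raise ParameterError("pre-emphasis must be in [0, 1)")
        if not self.frame_s > self.hop_s > 0:
            raise ParameterError("need frame_s > hop_s > 0")
        if self.n_ceps > self.n_mel_filters:
            raise ParameterError("n_ceps cannot exceed n_mel_filters")
        if self.log_floor <= 0:
            raise ParameterError("log floor must be > 0")


def pre_emphasis(x: np.ndarray, alpha: float = 0.97) -> np.ndarray:
    """s'(n) = s(n) - alpha * s(n-1); s'(0) = s(0)."""
    if not 0 <= alpha < 1:
        raise ParameterError("pre-emphasis coefficient must be in [0, 1)")
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ParameterError("pre-emphasis needs at least 2 samples")
    out = x.copy()
    out[1:] -= alpha * x[:-1]
    return out


def mel_scale(f: float | np.ndarray) -> float | np.ndarray:
    """m = 2595 * log10(1 + f/700)."""
    arr = np.asarray(f, dtype=float)
    if np.any(arr < 0):
        raise ParameterError("frequency must be >= 0")
    m = 2595.0 * np.log10(1.0 + arr / 700.0)
    return float(m) if np.isscalar(f) else m


def mel_to_hz(m: float | np.ndarray) -> float | np.ndarray:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, n_fft: int, sample_rate: float) -> np.ndarray:
    """Triangular filters with centers uniform in mel between 0 and Nyquist.

    Returns an (n_filters, n_fft//2 + 1) matrix acting on the one-sided power
    spectrum.
    """
    nyquist = sample_rate / 2.0
    mel_points = np.linspace(0.0, mel_scale(nyquist), n_filters + 2)
    hz_points = np.asarray(mel_to_hz(mel_points))
    bin_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    fb = np.zeros((n_filters, len(bin_freqs)))
    for i in range(n_filters):
        left, center, right = hz_points[i : i + 3]
        rising = (bin_freqs - left) / max(center - left, 1e-12)
        falling = (right - bin_freqs) / max(right - center, 1e-12)
        fb[i] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fb


def filterbank_centers_hz(n_filters: int, sample_rate: float) -> np.ndarray:
    mel_points = np.linspace(0.0, mel_scale(sample_rate / 2.0), n_filters + 2)
    return np.asarray(mel_to_hz(mel_points))[1:-1]


def _frame(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    n_frames = 1 + (len(x) - frame_len) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def mfcc(audio: np.ndarray, sample_rate: float, cfg: MfccConfig | None = None) -> np.ndarray:
    """Frames-by-coefficients MFCC matrix.

    Pipeline: pre-emphasis -> framing -> Hamming taper -> one-sided power
    spectrum -> triangular mel filterbank -> floored log -> orthonormal DCT-II,
    keeping the first ``n_ceps`` coefficients.
    """
    cfg = cfg or MfccConfig()
    audio = np.asarray(audio, dtype=float)
    frame_len = int(round(cfg.frame_s * sample_rate))
    hop = int(round(cfg.hop_s * sample_rate))
    if len(audio) < frame_len:
        raise ParameterError("audio shorter than one analysis frame")
    emphasized = pre_emphasis(audio, cfg.pre_emphasis)
    frames = _frame(emphasized, frame_len, hop) * np.hamming(frame_len)
    n_fft = 1 << max(frame_len - 1, 1).bit_length()  # next power of two >= frame_len
    power = np.abs(np.fft.rfft(frames, n=n_fft, axis=1)) ** 2
    fb = mel_filterbank(cfg.n_mel_filters, n_fft, sample_rate)
    energies = np.maximum(power @ fb.T, cfg.log_floor)
    log_energies = np.log(energies)
    ceps = sp_fft.dct(log_energies, type=2, norm="ortho", axis=1)
    return ceps[:, : cfg.n_ceps]


# ---------------------------------------------------------------------------
# steps and heading
# ---------------------------------------------------------------------------


def accel_magnitude(ax: np.ndarray, ay: np.ndarray, az: np.ndarray) -> np.ndarray:
    """M(n) = sqrt(ax^2 + ay^2 + az^2)."""
    ax, ay, az = (np.asarray(v, dtype=float) for v in (ax, ay, az))
    if not len(ax) == len(ay) == len(az):
        raise SchemaError("accelerometer axes have unequal lengths")
    return np.sqrt(ax**2 + ay**2 + az**2)


def detect_steps(
    magnitude: np.ndarray,
    sample_rate: float,
    min_prominence_factor: float = 0.5,
    min_period_s: float = 0.25,
) -> np.ndarray:
    """Indices of gait peaks: local maxima of the acceleration magnitude with
    prominence >= factor * std(magnitude) and spacing >= min_period_s."""
    if sample_rate <= 0:
        raise ParameterError("sample rate must be > 0")
    magnitude = np.asarray(magnitude, dtype=float)
    if magnitude.size == 0:
        return np.empty(0, dtype=int)
    sd = float(np.std(magnitude))
    if sd == 0.0:
        return np.empty(0, dtype=int)
    peaks, _ = signal.find_peaks(
        magnitude,
        prominence=min_prominence_factor * sd,
        distance=max(1, int(round(min_period_s * sample_rate))),
    )
    return peaks


def heading_angle(a: float, b: float) -> float:
    """theta = atan2(B, A) in degrees, in [-180, 180].

    ``a`` and ``b`` are the horizontal magnetometer components.
    """
    if a == 0.0 and b == 0.0:
        raise UndefinedMetricError("heading undefined for zero magnetic field")
    return float(np.degrees(np.arctan2(b, a)))


def mean_heading(mag_x: np.ndarray, mag_y: np.ndarray) -> float:
    """Circular mean of per-sample headings, in degrees."""
    theta = np.arctan2(np.asarray(mag_y, dtype=float), np.asarray(mag_x, dtype=float))
    s, c = np.mean(np.sin(theta)), np.mean(np.cos(theta))
    if s == 0.0 and c == 0.0:
        return 0.0
    return float(np.degrees(np.arctan2(s, c)))


# ---------------------------------------------------------------------------
# GPS trajectory
# ---------------------------------------------------------------------------


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in meters on a 6,371 km sphere."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def forward_bearing(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Initial great-circle azimuth from point 1 to point 2, degrees."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(lon2 - lon1)
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    return float(np.degrees(np.arctan2(y, x)))


def _wrap_deg(angle: float) -> float:
    return (angle + 180.0) % 360.0 - 180.0


@dataclass
class TrajectoryFeatures:
    total_distance_m: float = 0.0
    average_speed_ms: float = 0.0
    max_displacement_m: float = 0.0
    direction_change_sum_deg: float = 0.0
    step_count: int = 0
    mean_heading_deg: float = 0.0


def trajectory_features(
    track: np.ndarray, jitter_floor_m: float = 1.0
) -> TrajectoryFeatures:
    """Distance/speed/displacement/turning statistics of a (t, lat, lon) track.

    Bearings for the direction-change sum are only chained over legs longer
    than ``jitter_floor_m``, which suppresses compass noise from stationary
    GPS jitter.
    """
    track = np.asarray(track, dtype=float).reshape(-1, 3)
    if len(track) < 2:
        log.info("trajectory with %d fixes: motion features set to zero", len(track))
        return TrajectoryFeatures()
    t, lat, lon = track.T
    duration = t[-1] - t[0]
    if duration <= 0:
        raise ParameterError("track duration must be > 0")

    legs = [
        haversine_m(lat[i], lon[i], lat[i + 1], lon[i + 1]) for i in range(len(track) - 1)
    ]
    total = float(np.sum(legs))
    displacement = max(
        haversine_m(lat[0], lon[0], lat[i], lon[i]) for i in range(1, len(track))
    )

    bearings = [
        forward_bearing(lat[i], lon[i], lat[i + 1], lon[i + 1])
        for i in range(len(track) - 1)
        if legs[i] > jitter_floor_m
    ]
    turn_sum = float(
        np.sum([abs(_wrap_deg(b2 - b1)) for b1, b2 in zip(bearings, bearings[1:])])
    )
    return TrajectoryFeatures(
        total_distance_m=total,
        average_speed_ms=total / duration,
        max_displacement_m=float(displacement),
        direction_change_sum_deg=turn_sum,
    )


# ---------------------------------------------------------------------------
# per-window feature row
# ---------------------------------------------------------------------------


def extract_localization_features(
    window: SignalWindow,
    mfcc_config: MfccConfig | None = None,
    min_prominence_factor: float = 0.5,
    min_period_s: float = 0.25,
    jitter_floor_m: float = 1.0,
) -> tuple[list[str], np.ndarray]:
    """One named feature row per window.

    Concatenates the GPS trajectory features, step count and circular mean
    heading, per-channel skewness/kurtosis for every inertial channel present,
    and the mean-over-frames MFCC vector. Missing GPS or audio streams yield
    zero fills with a raised flag column so downstream models can tell "absent"
    from "measured zero".
    """
    mfcc_config = mfcc_config or MfccConfig()
    for ch in ("acc_x", "acc_y", "acc_z", "mag_x", "mag_y"):
        if ch not in window.channels:
            raise SchemaError(f"{window.window_id}: missing channel {ch!r}")

    names: list[str] = []
    values: list[float] = []

    gps_missing = len(window.gps_track) < 2
    traj = (
        TrajectoryFeatures()
        if gps_missing
        else trajectory_features(window.gps_track, jitter_floor_m)
    )
    names += [
        "traj_total_distance_m",
        "traj_average_speed_ms",
        "traj_max_displacement_m",
        "traj_direction_change_deg",
    ]
    values += [
        traj.total_distance_m,
        traj.average_speed_ms,
        traj.max_displacement_m,
        traj.direction_change_sum_deg,
    ]

    mag = accel_magnitude(
        window.channels["acc_x"], window.channels["acc_y"], window.channels["acc_z"]
    )
    steps = detect_steps(mag, window.sample_rate_hz, min_prominence_factor, min_period_s)
    names += ["step_count", "mean_heading_deg"]
    values += [
        float(len(steps)),
        mean_heading(window.channels["mag_x"], window.channels["mag_y"]),
    ]

    for ch in sorted(window.channels):
        x = window.channels[ch]
        names += [f"{ch}_skewness", f"{ch}_kurtosis"]
        if np.std(x) == 0.0:
            values += [0.0, 0.0]
        else:
            values += [skewness(x), kurtosis(x)]

    audio_missing = window.audio is None or len(window.audio) < int(
        round(mfcc_config.frame_s * (window.audio_sample_rate_hz or 0))
    )
    if audio_missing:
        coeffs = np.zeros(mfcc_config.n_ceps)
    else:
        coeffs = mfcc(window.audio, window.audio_sample_rate_hz, mfcc_config).mean(axis=0)
    names += [f"mfcc[{k}]" for k in range(mfcc_config.n_ceps)]
    values += [float(v) for v in coeffs]

    names += ["gps_missing", "audio_missing"]
    values += [float(gps_missing), float(audio_missing)]
    if gps_missing or audio_missing:
        log.debug("%s: neutral fill (gps=%s audio=%s)", window.window_id, gps_missing, audio_missing)
    return names, np.asarray(values, dtype=float)
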