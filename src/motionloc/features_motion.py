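"""Physical-activity features from inertial windows.

Per channel: Shannon entropy of the sample histogram, skewness and excess
kurtosis (population moments). Per accelerometer axis: linear prediction
cepstral coefficients (LPCC) from an all-pole model fitted with the
Levinson-Durbin recursion on the biased autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import INERTIAL_CHANNELS, SignalWindow
from .errors import DegenerateSignalError, ParameterError, SchemaError


def shannon_entropy(x: np.ndarray, n_bins: int = 16) -> float:
    """H = -sum p_i log2 p_i over an equal-width histogram of the window.

    Bins span [min, max] of the window itself; a constant window occupies a
    single bin and has zero entropy. 0 <= H <= log2(n_bins).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ParameterError("entropy of an empty window is undefined")
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    if np.ptp(x) == 0.0:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


@dataclass(frozen=True)
class LpcModel:
    """All-pole model s(n) = sum_k a_k s(n-k) + e(n)."""

    order: int
    coefficients: np.ndarray  # a_1 .. a_p
    prediction_error_power: float  # G

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ParameterError("LPC order must be >= 1")
        if self.prediction_error_power < 0:
            raise ParameterError("prediction error power must be >= 0")


def _autocorrelation(x: np.ndarray, lags: int) -> np.ndarray:
    """Biased autocorrelation r[0..lags]."""
    n = len(x)
    full = np.correlate(x, x, mode="full")
    return full[n - 1 : n + lags] / n


def lpc_fit(x: np.ndarray, p: int = 12) -> LpcModel:
    """Levinson-Durbin solve of the Yule-Walker equations at order p."""
    x = np.asarray(x, dtype=float)
    if len(x) <= 2 * p:
        raise ParameterError(f"window of {len(x)} samples too short for LPC order {p}")
    r = _autocorrelation(x, p)
    if r[0] <= 0.0:
        raise DegenerateSignalError("zero-energy window; LPC undefined")

    a = np.zeros(p)
    err = r[0]
    for m in range(1, p + 1):
        acc = r[m] - np.dot(a[: m - 1], r[m - 1 : 0 : -1])
        if err <= 0.0:
            raise DegenerateSignalError("Levinson-Durbin error power collapsed to zero")
        k = acc / err
        a_new = a.copy()
        a_new[m - 1] = k
        a_new[: m - 1] = a[: m - 1] - k * a[: m - 1][::-1]
        a = a_new
        err *= 1.0 - k * k
    return LpcModel(order=p, coefficients=a, prediction_error_power=float(max(err, 0.0)))


def lpcc(model: LpcModel, n_ceps: int = 12) -> np.ndarray:
    """Cepstral coefficients c_1..c_n of the all-pole model.

    c_0 = ln G (the log prediction-error power) seeds the recursion
    c_m = a_m + sum_{k=1}^{m-1} (k/m) c_k a_{m-k}, with a_m = 0 beyond the
    model order.
    """
    if model.prediction_error_power <= 0.0:
        raise DegenerateSignalError("zero prediction-error power; LPCC undefined")
    a = model.coefficients
    c = np.zeros(n_ceps + 1)
    c[0] = np.log(model.prediction_error_power)
    for m in range(1, n_ceps + 1):
        val = a[m - 1] if m <= model.order else 0.0
        for k in range(1, m):
            if m - k <= model.order:
                val += (k / m) * c[k] * a[m - k - 1]
        c[m] = val
    return c[1:]


def skewness(x: np.ndarray) -> float:
    """Population skewness (1/N) sum ((x - mu)/sigma)^3."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ParameterError("skewness needs at least 3 samples")
    if np.std(x) == 0.0:
        raise DegenerateSignalError("constant window; skewness undefined")
    return float(stats.skew(x, bias=True))


def kurtosis(x: np.ndarray) -> float:
    """Population excess kurtosis E[((x - mu)/sigma)^4] - 3."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ParameterError("kurtosis needs at least 2 samples")
    if np.std(x) == 0.0:
        raise DegenerateSignalError("constant window; kurtosis undefined")
    return float(stats.kurtosis(x, bias=True, fisher=True))


#: channels that get LPCCs by default (accelerometer axes)
DEFAULT_LPCC_CHANNELS = ("acc_x", "acc_y", "acc_z")


def extract_physical_features(
    window: SignalWindow,
    entropy_bins: int = 16,
    lpc_order: int = 12,
    n_lpcc: int = 12,
    lpcc_channels: tuple[str, ...] = DEFAULT_LPCC_CHANNELS,
) -> tuple[list[str], np.ndarray]:
    """One named feature row per window: entropy/skew/kurt per channel plus
    LPCCs per configured accelerometer axis."""
    for ch in INERTIAL_CHANNELS:
        if ch not in window.channels:
            raise SchemaError(f"{window.window_id}: missing channel {ch!r}")
    names: list[str] = []
    values: list[float] = []
    try:
        for ch in INERTIAL_CHANNELS:
            x = window.channels[ch]
            names += [f"{ch}_entropy", f"{ch}_skewness", f"{ch}_kurtosis"]
            values += [shannon_entropy(x, entropy_bins), skewness(x), kurtosis(x)]
        for ch in lpcc_channels:
            if ch not in window.channels:
                raise SchemaError(f"{window.window_id}: missing channel {ch!r}")
            ceps = lpcc(lpc_fit(window.channels[ch], lpc_order), n_lpcc)
            names += [f"{ch}_lpcc[{k}]" for k in range(1, n_lpcc + 1)]
            values += [float(v) for v in ceps]
    except DegenerateSignalError as exc:
        raise DegenerateSignalError(f"{window.window_id}: {exc}") from exc
    return names, np.asarray(values, dtype=float)
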