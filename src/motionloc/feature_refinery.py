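"""Feature selection, class balancing and distribution optimization.

The refinery is the fit/apply boundary of the pipeline: variance-threshold
selection, a per-feature Yeo-Johnson power transform with maximum-likelihood
lambda, and standardization are all fitted on training rows only and replayed
on test rows from the stored state. Class balancing operates one level below,
on raw signal windows, by segment-permutation augmentation.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import yeojohnson_llf

from .core_io import FeatureMatrix, SignalWindow
from .errors import (
    AugmentationError,
    DegenerateSignalError,
    EmptySelectionError,
    ParameterError,
    SchemaError,
)

LAMBDA_BOUNDS = (-5.0, 5.0)


def feature_variance(column: np.ndarray) -> float:
    """Population variance (1/n) sum (x_i - xbar)^2."""
    column = np.asarray(column, dtype=float)
    if column.size == 0:
        raise ParameterError("variance of an empty column is undefined")
    return float(np.var(column))


@dataclass
class RefineryState:
    """Fitted state: kept columns, per-feature lambda, and standardization."""

    kept_features: list[str]
    variance_threshold: float
    lambdas: np.ndarray | None = None
    means: np.ndarray | None = None
    stds: np.ndarray | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "kept_features": self.kept_features,
                "variance_threshold": self.variance_threshold,
                "lambdas": None if self.lambdas is None else list(map(float, self.lambdas)),
                "means": None if self.means is None else list(map(float, self.means)),
                "stds": None if self.stds is None else list(map(float, self.stds)),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RefineryState":
        d = json.loads(text)
        arr = lambda v: None if v is None else np.asarray(v, dtype=float)
        return cls(
            kept_features=list(d["kept_features"]),
            variance_threshold=float(d["variance_threshold"]),
            lambdas=arr(d["lambdas"]),
            means=arr(d["means"]),
            stds=arr(d["stds"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RefineryState":
        return cls.from_json(Path(path).read_text())


def select_by_variance(
    fm: FeatureMatrix, threshold: float = 0.0
) -> tuple[FeatureMatrix, RefineryState]:
    """Keep exactly the features whose variance exceeds the threshold."""
    if fm.n_rows == 0:
        raise ParameterError("cannot select features from an empty matrix")
    kept = [
        name
        for j, name in enumerate(fm.feature_names)
        if feature_variance(fm.rows[:, j]) > threshold
    ]
    if not kept:
        raise EmptySelectionError(
            f"variance threshold {threshold} removed every feature; lower the threshold"
        )
    return fm.select(kept), RefineryState(kept_features=kept, variance_threshold=threshold)


# ---------------------------------------------------------------------------
# permutation augmentation
# ---------------------------------------------------------------------------


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def _split_points(n: int, k: int) -> list[tuple[int, int]]:
    """k contiguous equal-length segments; the remainder joins the last one."""
    size = n // k
    bounds = [(i * size, (i + 1) * size) for i in range(k)]
    bounds[-1] = (bounds[-1][0], n)
    return bounds


def permute_window(window: SignalWindow, k_segments: int = 3, rng_seed=None) -> SignalWindow:
    """New window whose channels are a non-identity rearrangement of k
    contiguous segments; the same permutation applies to every channel (and to
    the audio clip), so cross-channel structure within a segment is kept."""
    if k_segments < 2:
        raise ParameterError("need at least 2 segments to permute")
    n = window.n_samples
    if k_segments > n:
        raise ParameterError(f"{k_segments} segments exceed window length {n}")
    rng = _as_rng(rng_seed)
    perm = np.arange(k_segments)
    while np.array_equal(perm, np.arange(k_segments)):
        perm = rng.permutation(k_segments)

    def rearrange(x: np.ndarray) -> np.ndarray:
        bounds = _split_points(len(x), k_segments)
        return np.concatenate([x[bounds[i][0] : bounds[i][1]] for i in perm])

    channels = {name: rearrange(x) for name, x in window.channels.items()}
    audio = None
    if window.audio is not None and len(window.audio) >= k_segments:
        audio = rearrange(window.audio)
    elif window.audio is not None:
        audio = window.audio.copy()
    return SignalWindow(
        source_id=window.source_id,
        channels=channels,
        start_time=window.start_time,
        duration=window.duration,
        sample_rate_hz=window.sample_rate_hz,
        label=window.label,
        augmented=True,
        gps_track=window.gps_track.copy(),
        audio=audio,
        audio_sample_rate_hz=window.audio_sample_rate_hz,
    )


def balance_classes(
    windows: Sequence[SignalWindow], k_segments: int = 3, rng_seed=None
) -> list[SignalWindow]:
    """Augment every minority class with permuted copies of its own windows
    until all class counts equal the majority count. Originals are untouched
    and come first in the output."""
    labels = [w.label for w in windows]
    counts = Counter(labels)
    if len(counts) < 2:
        raise ParameterError("balancing needs at least 2 classes")
    majority = max(counts.values())
    rng = _as_rng(rng_seed)
    out = list(windows)
    for label in sorted(counts):
        deficit = majority - counts[label]
        if deficit == 0:
            continue
        sources = [w for w in windows if w.label == label]
        for i in range(deficit):
            src = sources[i % len(sources)]
            try:
                out.append(permute_window(src, k_segments, rng))
            except ParameterError as exc:
                raise AugmentationError(f"class {label!r}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Yeo-Johnson
# ---------------------------------------------------------------------------


def yeo_johnson(x, lam: float):
    """Monotone power transform psi(x; lambda), defined for all real x.

    x >= 0: ((x+1)^lam - 1)/lam, or ln(x+1) when lam = 0.
    x <  0: -((-x+1)^(2-lam) - 1)/(2-lam), or -ln(-x+1) when lam = 2
    (the sign on the lam = 2 branch keeps the map strictly increasing and
    continuous in both arguments).
    """
    arr = np.asarray(x, dtype=float)
    out = np.empty_like(arr)
    pos = arr >= 0
    if lam == 0.0:
        out[pos] = np.log1p(arr[pos])
    else:
        out[pos] = (np.power(arr[pos] + 1.0, lam) - 1.0) / lam
    if lam == 2.0:
        out[~pos] = -np.log1p(-arr[~pos])
    else:
        out[~pos] = -(np.power(-arr[~pos] + 1.0, 2.0 - lam) - 1.0) / (2.0 - lam)
    return float(out) if np.isscalar(x) else out


def fit_lambda(column: np.ndarray) -> float:
    """Maximum-likelihood lambda via bounded scalar search on [-5, 5].

    Maximizes the Gaussian profile log-likelihood of the transformed column,
    Jacobian term included.
    """
    column = np.asarray(column, dtype=float)
    if len(column) < 10:
        raise ParameterError("lambda estimation needs at least 10 samples")
    if np.ptp(column) == 0.0:
        raise DegenerateSignalError("constant column; lambda undefined")
    res = optimize.minimize_scalar(
        lambda lam: -yeojohnson_llf(lam, column),
        bounds=LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# fit / apply
# ---------------------------------------------------------------------------


def fit_refinery(fm: FeatureMatrix, threshold: float = 0.0) -> RefineryState:
    """Fit selection, per-feature lambda, and post-transform standardization
    on (training) rows."""
    selected, state = select_by_variance(fm, threshold)
    lambdas = np.array([fit_lambda(selected.rows[:, j]) for j in range(len(state.kept_features))])
    transformed = np.column_stack(
        [yeo_johnson(selected.rows[:, j], lambdas[j]) for j in range(len(lambdas))]
    )
    means = transformed.mean(axis=0)
    stds = transformed.std(axis=0)
    if np.any(stds <= 0):
        bad = state.kept_features[int(np.argmin(stds))]
        raise DegenerateSignalError(f"feature {bad!r} constant after transform")
    state.lambdas, state.means, state.stds = lambdas, means, stds
    return state


def apply_refinery(fm: FeatureMatrix, state: RefineryState) -> FeatureMatrix:
    """Replay selection -> psi(.; lambda) -> standardization from stored state."""
    if state.lambdas is None or state.means is None or state.stds is None:
        raise SchemaError("refinery state is not fully fitted")
    selected = fm.select(state.kept_features)  # raises SchemaError on unseen names
    cols = [
        (yeo_johnson(selected.rows[:, j], state.lambdas[j]) - state.means[j]) / state.stds[j]
        for j in range(len(state.kept_features))
    ]
    return FeatureMatrix(
        feature_names=list(state.kept_features),
        rows=np.column_stack(cols) if cols else np.empty((fm.n_rows, 0)),
        labels=fm.labels,
        augmented_flags=fm.augmented_flags,
        row_ids=fm.row_ids,
    )
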