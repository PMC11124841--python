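"""Structured pipeline configuration.

A single YAML file carries per-stage sections; any key may be omitted, in
which case the documented default applies. Command-line flags override file
values.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import ConfigError

DEFAULTS: dict = {
    "filter": {"order": 4, "cutoff_hz": 10.0},
    "window": {"seconds": 5.0, "overlap": 0.5, "taper": True},
    "features": {
        "entropy_bins": 16,
        "lpc_order": 12,
        "n_lpcc": 12,
        "lpcc_channels": ["acc_x", "acc_y", "acc_z"],
    },
    "mfcc": {
        "pre_emphasis": 0.97,
        "frame_s": 0.025,
        "hop_s": 0.010,
        "n_mel_filters": 26,
        "n_ceps": 13,
        "log_floor": 1e-10,
    },
    "steps": {"min_prominence_factor": 0.5, "min_period_s": 0.25},
    "traj": {"jitter_floor_m": 1.0},
    "refinery": {"variance_threshold": 0.0, "k_segments": 3, "balance": True},
    "mlp": {
        "hidden_sizes": [64, 64, 32],
        "batch_size": 32,
        "max_epochs": 100,
        "patience": 10,
        "validation_fraction": 0.2,
        "learning_rate": 0.01,
    },
    "evaluation": {"k_folds": 5},
    "synthetic": {
        "duration_s": 30.0,
        "inertial_rate_hz": 32.0,
        "gps_rate_hz": 1.0,
        "audio_rate_hz": 4000.0,
        "noise_sd": 0.05,
        "gps_jitter_m": 3.0,
        "recordings_per_class": 10,
        "physical_classes": ["sit", "stand", "walk", "run"],
        "localization_classes": ["indoor", "outdoor", "vehicle"],
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    merged = dict(base)
    for key, value in override.items():
        if key not in base:
            raise ConfigError(f"unknown config key {key!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config section {key!r} must be a mapping")
            merged[key] = _deep_merge(base[key], value)
        else:
            merged[key] = value
    return merged


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    if path is None:
        return {k: dict(v) if isinstance(v, dict) else v for k, v in DEFAULTS.items()}
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    loaded = yaml.safe_load(path.read_text()) or {}
    if not isinstance(loaded, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return _deep_merge(DEFAULTS, loaded)
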