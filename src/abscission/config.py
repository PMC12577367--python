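"""Run configuration: defaults, YAML loading, strict key validation.

The effective configuration (defaults merged with the user file) is
written alongside every run's outputs together with a content hash, so
any output table can be traced back to the exact parameter set that
produced it.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .exceptions import ConfigError

DEFAULTS: dict = {
    "input": None,                # path to movie / stack / table
    "annotations": None,          # path to axis or seed-ROI CSV
    "output_dir": "abscission_out",
    "seed": 0,
    "channels": None,             # role -> index override for plain TIFFs
    "pixel_size_um": None,        # calibration overrides
    "frame_interval_min": None,
    "simulate": {
        "preset": "hela",         # "hela" | "yeast"
        "params": {},             # SceneParams field overrides
    },
    "segmentation": {
        "threshold": "otsu",      # "otsu" or a number
        "nucleus_threshold": "otsu",
        "min_area_px": 20,
        "min_object_px": 4,
        "baseline_frames": 5,
        "elongation_factor": 1.5,
        "persistence_frames": 2,
        "rpa_k": 3.0,
        "min_separation_px": 3,
    },
    "actin": {
        "threshold": "otsu",
        "top_fraction": 0.05,
        "min_positive_px": 20,
        "epsilon": 1e-6,
        "com_weighting": "intensity",   # "intensity" | "unweighted"
        "tau_rel": 0.5,
        "tau_abs": 2.0,
        "k_frames": 2,
    },
    "profile": {
        "half_width_px": 2,
        "prominence_rel": 0.25,
        "min_separation_um": 0.4,
        "persistence_frames": 2,
        "ingression_fraction": 0.6,
        "z_aggregate": "max",
    },
    "midbody": {
        "focus_criterion": "variance",
        "background": 0.0,
    },
    "stats": {
        "horizon_min": 60.0,
        "plots": False,
    },
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key: {where}")
        if isinstance(defaults[key], dict) and not key.endswith("params"):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {where} must be a mapping")
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Build the effective config from defaults, a YAML file and overrides."""
    config = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must contain a mapping")
        config = _merge(config, user)
    if overrides:
        config = _merge(config, overrides)
    return config


def config_hash(config: dict) -> str:
    """Stable short hash of the effective configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_effective_config(config: dict, output_dir) -> Path:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "effective_config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return path
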