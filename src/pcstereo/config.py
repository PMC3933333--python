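"""Run configuration: YAML file -> validated, defaults-filled dict.

An empty or missing-section config falls back to the calibrated default
parameter set (the published assay design and the default cohort effects).
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .defaults import REGION_CALIBRATIONS
from .sampling import DEFAULT_GRID_PITCH


class ConfigError(ValueError):
    """Invalid configuration; the message carries the field path."""


DEFAULT_CONFIG = {
    "seed": 0,
    "regions": list(REGION_CALIBRATIONS),
    "sampling": {
        "frame_area": 19600.0,
        "guard_depth": 5.0,
        "disector_height": 75.0,
        "grid_pitch": dict(DEFAULT_GRID_PITCH),
        "thickness": 200.0,
        "period": 6,
    },
    "degradation": {
        "loss_fraction": 0.0,
        "fray_depth_um": 0.0,
    },
    "phantom": {
        "replicates": 1,
    },
    "cohort": {
        "n_cohorts": 1,
        "mode": "fast_surrogate",
        "with_adir": True,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config field: {where}")
        if isinstance(base[key], dict) and key != "grid_pitch":
            if not isinstance(val, dict):
                raise ConfigError(f"{where}: expected a mapping")
            out[key] = _merge(base[key], val, where)
        else:
            out[key] = copy.deepcopy(val)
    return out


def validate_config(path: str | Path | None = None,
                    overrides: dict | None = None) -> dict:
    """Load, merge with defaults, and validate a run configuration.

    An empty file (or path=None) yields the full calibrated default config.
    """
    user: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        text = p.read_text()
        loaded = yaml.safe_load(text) if text.strip() else None
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        user = loaded
    cfg = _merge(DEFAULT_CONFIG, user)
    if overrides:
        cfg = _merge(cfg, overrides)

    samp = cfg["sampling"]
    side = samp["frame_area"] ** 0.5
    for name, pitch in samp["grid_pitch"].items():
        if name not in REGION_CALIBRATIONS:
            raise ConfigError(f"sampling.grid_pitch: unknown region {name!r}")
        if pitch < side:
            raise ConfigError(
                f"sampling.grid_pitch.{name}: pitch {pitch} um below the "
                f"frame side {side:.0f} um (frames would overlap)"
            )
    for name in cfg["regions"]:
        if name not in REGION_CALIBRATIONS:
            raise ConfigError(f"regions: unknown region {name!r}")
    if samp["guard_depth"] + samp["disector_height"] > samp["thickness"]:
        raise ConfigError(
            "sampling: guard_depth + disector_height exceeds thickness"
        )
    if not (0 <= cfg["degradation"]["loss_fraction"] < 1):
        raise ConfigError("degradation.loss_fraction must be in [0, 1)")
    if cfg["cohort"]["mode"] not in ("fast_surrogate", "full_pipeline"):
        raise ConfigError("cohort.mode must be fast_surrogate|full_pipeline")
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable hash embedded in every output for provenance."""
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
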