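"""Run configuration: YAML loading, defaults, provenance hashing.

A run config drives the command-line pipeline. All times are hours, doses
Gy, confluence dimensionless; seeds are recorded in every output artifact
together with the SHA-256 hash of the canonical config.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .params import GrowthParams
from .synthetic import TruthConfig, default_truth

__all__ = ["load_config", "config_hash", "truth_from_config", "growth_from_config"]

_DEFAULTS = {
    "seed": 0,
    "dt": 0.01,
    "gate_sharpness": 1.0,
    "generator": {},
    "split": {"fraction": 0.75},
    "calibration": {"model": 3, "n_starts": 4, "max_nfev": 800},
    "selection": {"sample_count": "curves", "n_starts": 2, "max_nfev": 300},
}

_GENERATOR_FIELDS = {
    "replicates_per_condition",
    "noise_cv",
    "heterogeneity_cv",
    "schedules",
    "horizon",
    "n0_levels",
    "generating_model",
    "sampling_interval",
    "media_period",
    "media_loss_range",
}


def load_config(path) -> dict:
    """Load a YAML run config, merge defaults, and validate referenced paths."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    config = {}
    for key, default in _DEFAULTS.items():
        if isinstance(default, dict):
            config[key] = {**default, **raw.get(key, {})}
        else:
            config[key] = raw.get(key, default)
    for key in raw:
        if key not in config:
            config[key] = raw[key]
    for name in ("curves", "kinetics"):
        ref = config.get("data", {}).get(name) if isinstance(config.get("data"), dict) else None
        if ref is not None and not Path(ref).exists():
            raise ConfigurationError(f"{path}: referenced {name} file {ref!r} missing")
    return config


def config_hash(config: dict) -> str:
    """SHA-256 of the canonical JSON form of the config."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def truth_from_config(config: dict) -> TruthConfig:
    """Build the generator truth from the ``generator`` section.

    ``cell_lines`` selects a subset of the built-in ground-truth presets;
    scalar TruthConfig fields may be overridden directly.
    """
    gen = dict(config.get("generator") or {})
    names = gen.pop("cell_lines", None)
    overrides = {}
    for key, value in gen.items():
        if key not in _GENERATOR_FIELDS:
            raise ConfigurationError(f"unknown generator option {key!r}")
        if key in ("schedules", "n0_levels", "sampling_interval", "media_loss_range"):
            value = tuple(value)
        overrides[key] = value
    overrides["dt"] = config.get("dt", 0.01)
    overrides["gate_sharpness"] = config.get("gate_sharpness", 1.0)
    truth = default_truth(**overrides)
    if names:
        missing = [n for n in names if n not in truth.cell_lines]
        if missing:
            raise ConfigurationError(f"unknown cell line preset(s) {missing}")
        from dataclasses import replace

        truth = replace(
            truth, cell_lines={n: truth.cell_lines[n] for n in names}
        )
    return truth


def growth_from_config(config: dict) -> dict:
    """Per-cell-line GrowthParams from the ``growth`` section (file-data runs)."""
    section = config.get("growth")
    if not section:
        raise ConfigurationError("config lacks a 'growth' section")
    return {
        name: GrowthParams(**{k: float(v) for k, v in entry.items()})
        for name, entry in section.items()
    }
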