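"""Validated run configuration.

A configuration is a nested mapping with four sections (``calibration``,
``simulate``, ``quantify``, ``events``, ``io``).  :func:`load_config` merges a
YAML/JSON document over the defaults, rejects unknown keys and range-checks
every numeric parameter.  An empty document yields the full default
configuration.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["ConfigError", "default_config", "load_config", "validate_config"]


class ConfigError(ValueError):
    """A configuration document violated the schema."""


# (default, type, min, max, allowed-values) per leaf; None bounds mean unchecked.
# A float minimum of 0.0 is exclusive when marked in _STRICT_POSITIVE.
_STRICT_POSITIVE = {
    "dx_um", "dz_um", "dt_min", "box_xy_um", "box_z_um",
    "packet_search_radius_um", "stage2_sep_um", "half_length_um",
}

_SCHEMA: dict[str, dict[str, tuple]] = {
    "calibration": {
        "dx_um": (0.15, float, 0.0, None, None),
        "dz_um": (0.5, float, 0.0, None, None),
        "dt_min": (1.0, float, 0.0, None, None),
        "t0_event": (0, int, 0, None, None),
    },
    "simulate": {
        "condition": ("control", str, None, None,
                      ("control", "gpr12_rnai", "csnk1_rnai", "let92_rnai")),
        "seed": (1, int, 0, None, None),
        "noise": (True, bool, None, None, None),
        "pre_event_frames": (0, int, 0, None, None),
    },
    "quantify": {
        "n_points": (10, int, 1, None, None),
        "exclusion_radius_um": (1.0, float, 0.0, None, None),
        "smooth_sigma_px": (1.0, float, 0.0, None, None),
        "box_xy_um": (6.0, float, 0.0, None, None),
        "box_z_um": (4.0, float, 0.0, None, None),
        "dilate_um": (0.6, float, 0.0, None, None),
        "min_packet_voxels": (3, int, 1, None, None),
        "packet_search_radius_um": (5.0, float, 0.0, None, None),
    },
    "events": {
        "min_drop_frac": (0.10, float, 0.0, 1.0, None),
        "persistence": (2, int, 1, None, None),
        "volume_drop_frac": (0.15, float, 0.0, 1.0, None),
        "min_hole_voxels": (4, int, 1, None, None),
        "stage_min_sep_px": (2.0, float, 1.0, None, None),
        "stage_dip_frac": (0.20, float, 0.0, 1.0, None),
        "stage2_sep_um": (1.0, float, 0.0, None, None),
    },
    "io": {
        "dtype": ("float32", str, None, None, ("float32", "uint16")),
        "clip": (False, bool, None, None, None),
    },
    "geometry": {
        "n_angles": (36, int, 1, None, None),
        "half_length_um": (2.5, float, 0.0, None, None),
        "baseline_frac": (0.10, float, 0.0, 0.5, None),
    },
}


def default_config() -> dict[str, dict[str, Any]]:
    """The full default configuration as a nested dict."""
    return {sec: {k: v[0] for k, v in leaves.items()} for sec, leaves in _SCHEMA.items()}


def _check_leaf(section: str, key: str, value: Any) -> Any:
    _, typ, lo, hi, allowed = _SCHEMA[section][key]
    if typ is float and isinstance(value, int) and not isinstance(value, bool):
        value = float(value)
    if typ is bool and not isinstance(value, bool):
        raise ConfigError(f"{section}.{key}: expected a boolean, got {value!r}")
    if typ is int and (isinstance(value, bool) or not isinstance(value, int)):
        raise ConfigError(f"{section}.{key}: expected an integer, got {value!r}")
    if not isinstance(value, typ):
        raise ConfigError(f"{section}.{key}: expected {typ.__name__}, got {value!r}")
    if lo is not None and value < lo:
        raise ConfigError(f"{section}.{key}: {value!r} is below the minimum {lo}")
    if key in _STRICT_POSITIVE and value <= 0:
        raise ConfigError(f"{section}.{key}: must be strictly positive, got {value!r}")
    if hi is not None and value > hi:
        raise ConfigError(f"{section}.{key}: {value!r} exceeds the maximum {hi}")
    if allowed is not None and value not in allowed:
        raise ConfigError(f"{section}.{key}: {value!r} not one of {allowed}")
    return value


def validate_config(document: Mapping[str, Any] | None) -> dict[str, dict[str, Any]]:
    """Merge ``document`` over the defaults and validate every field."""
    cfg = default_config()
    if document is None:
        return cfg
    if not isinstance(document, Mapping):
        raise ConfigError(f"configuration must be a mapping, got {type(document).__name__}")
    for section, leaves in document.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown configuration section {section!r}; "
                              f"valid sections: {sorted(_SCHEMA)}")
        if leaves is None:
            continue
        if not isinstance(leaves, Mapping):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key, value in leaves.items():
            if key not in _SCHEMA[section]:
                raise ConfigError(f"unknown key {section}.{key}; "
                                  f"valid keys: {sorted(_SCHEMA[section])}")
            cfg[section][key] = _check_leaf(section, key, value)
    return cfg


def load_config(path: str | Path | None = None) -> dict[str, dict[str, Any]]:
    """Load and validate a YAML or JSON configuration file.

    ``path=None`` or an empty document returns the full default configuration.
    """
    if path is None:
        return validate_config(None)
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        document = json.loads(text) if text.strip() else None
    else:
        document = yaml.safe_load(text)
    return validate_config(document)
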