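"""Run configuration: YAML schema, defaults and validation.

One YAML file carries everything an analysis run needs — arena geometry and
pixel calibration, pod/limb marker maps, frame rates, thresholds and bin
widths.  Frame rates have no defaults on purpose: the acquisition rates are
properties of the recording hardware and must be declared.
"""

from __future__ import annotations

import hashlib
import json
from typing import Any, Mapping

import yaml

from .openfield import ArenaGeometry


class ConfigError(ValueError):
    """A required key is missing or a value violates its constraint."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"config key {key!r}: {message}")


DEFAULTS: dict[str, Any] = {
    "arena": {
        "side_length": 1.83,
        "door_wall": "S",
        "door_center": 0.915,
        "door_zone_depth": 0.30,
        "px_per_meter": 300.0,
        "origin_px": [0.0, 549.0],
        "y_down": True,
    },
    "pose": {"confidence_threshold": 0.9, "max_gap": 10, "bodypart": "head_back"},
    "heatmap": {"n_bins": 61},
    "circadian": {
        "bin_width": 15,
        "peak_window": 240,
        "sleep_threshold": 0.0,
        "sleep_min_run": 4,
        "evening_window": [19.0, 3.0],
        "morning_window": [5.0, 11.0],
    },
    "gait": {
        "front_marker_index": 0,
        "lowpass_cutoff": 3.0,
        "velocity_pod": "shoulders",
        "stance_height_frac": 0.15,
        "speed_frac": 0.10,
    },
}

# dotted paths that each subcommand cannot run without
REQUIRED: dict[str, list[str]] = {
    "openfield": ["frame_rate", "arena.side_length", "arena.px_per_meter"],
    "gait": ["frame_rate", "gait.pods", "gait.limbs"],
    "circadian": ["circadian.bin_width"],
    "nor": [],
    "ballpit": [],
    "simulate": [],
    "trends": [],
}


def load_config(path: str | None) -> dict:
    """Read a YAML config and layer it over the defaults."""
    cfg = _deep_copy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise ConfigError("<root>", "config file must hold a mapping")
        _deep_update(cfg, user)
    return cfg


def validate_config(cfg: Mapping, subcommand: str) -> None:
    """Check required keys and value constraints; raises :class:`ConfigError`."""
    for dotted in REQUIRED.get(subcommand, []):
        node: Any = cfg
        for part in dotted.split("."):
            if not isinstance(node, Mapping) or part not in node:
                raise ConfigError(dotted, "missing required key")
            node = node[part]
    if "frame_rate" in cfg and not (isinstance(cfg["frame_rate"], (int, float)) and cfg["frame_rate"] > 0):
        raise ConfigError("frame_rate", "must be a positive number")
    arena = cfg.get("arena", {})
    for key in ("side_length", "px_per_meter", "door_zone_depth"):
        if key in arena and not arena[key] > 0:
            raise ConfigError(f"arena.{key}", "must be > 0")
    pose = cfg.get("pose", {})
    if "confidence_threshold" in pose and not 0 <= pose["confidence_threshold"] <= 1:
        raise ConfigError("pose.confidence_threshold", "must be in [0, 1]")


def arena_from_config(cfg: Mapping) -> ArenaGeometry:
    a = cfg["arena"]
    return ArenaGeometry(
        side_length=a["side_length"],
        door_wall=a.get("door_wall", "S"),
        door_center=a.get("door_center", a["side_length"] / 2.0),
        door_zone_depth=a.get("door_zone_depth", 0.30),
        px_per_meter=a["px_per_meter"],
        origin_px=tuple(a.get("origin_px", (0.0, 0.0))),
        y_down=a.get("y_down", True),
    )


def config_hash(cfg: Mapping) -> str:
    """Stable short hash recorded in every report (reproducibility trail)."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _deep_copy(d):
    return json.loads(json.dumps(d))


def _deep_update(base: dict, extra: Mapping) -> None:
    for k, v in extra.items():
        if isinstance(v, Mapping) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
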