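"""System configuration: one human-editable YAML file.

All tunables live here rather than in code: the sensor catalogue, the
chosen sensor/lens assembly, stereo rig parameters, detection
thresholds, CNN hyper-parameters, size-class boundaries, the action
policy and the sync/matching constants.  ``load_config`` validates the
schema strictly — unknown keys are rejected by name, missing required
keys reported by name — and applies defaults for everything optional.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path

import yaml

from .decision import ActionPolicy, SizeClassBoundaries
from .detection import DetectionParams
from .identification import CnnConfig
from .optics import LensSpec, OpticalAssembly, SensorSpec
from .stereo import StereoRig

__all__ = ["SystemConfig", "ConfigError", "DEFAULT_CONFIG", "load_config", "save_config"]


class ConfigError(ValueError):
    """Schema violation in a config file; the message names the key."""


DEFAULT_CONFIG: dict = {
    "sensor_catalog": {
        "C1": {"vsr_h": 3280, "vsr_v": 2464, "vss_h": 3.680, "vss_v": 2.760},
        "C2": {"vsr_h": 4056, "vsr_v": 3040, "vss_h": 6.287, "vss_v": 4.712},
        "C3": {"vsr_h": 4208, "vsr_v": 3120, "vss_h": 6.300, "vss_v": 5.700},
        "C4": {"vsr_h": 4912, "vsr_v": 3684, "vss_h": 7.660, "vss_v": 4.560},
    },
    "assembly": {"sensor": "C1", "f_mm": 3.0},
    "rig": {
        "baseline": 1.0,
        "vsr_axis": 3280,
        "fov_axis_deg": 63.0,
        "tilt_alpha_deg": None,
    },
    "detection": {
        "blur_kernel": 5,
        "blur_sigma": 1.5,
        "diff_thresh": 25,
        "merge_kernel": 9,
        "merge_sigma": 2.0,
        "binary_thresh": 100,
        "min_w": 12,
        "min_h": 2,
        "crop_size": 100,
    },
    "cnn": {
        "lc1": 32,
        "lc2": 32,
        "lfc1": 128,
        "n_classes": 2,
        "kernel": 3,
        "pool": 2,
        "learning_rate": 1.0e-5,
        "adam_epsilon": 1.0e-7,
        "epochs": 50,
        "validation_split": 0.1,
        "batch_size": 32,
    },
    "classes": {
        "wingspan": [0.68, 1.26, 1.505],
        "height": [0.32, 0.40, 0.555],
        "area": [0.11, 0.25, 0.415],
    },
    "policy": {
        "strobe": {"small": 300.0, "medium": 300.0, "large": 300.0},
        "audio": {"small": 300.0, "medium": 300.0, "large": 300.0},
        "turbine_stop": {"large": 200.0},
    },
    "matching": {
        "max_center_offset_px": 150.0,
        "min_disparity_px": 1.0,
        "sync_tolerance_s": 0.05,
    },
    "paths": {"archive": "events", "media": "media"},
    "seed": 0,
}

#: keys that must be present explicitly (no silent default)
_REQUIRED = [("rig", "baseline")]


def _merge_checked(default: dict, user: dict, prefix: str = "") -> dict:
    out = copy.deepcopy(default)
    for key, value in user.items():
        path = f"{prefix}{key}"
        if key == "sensor_catalog" and prefix == "":
            # free-form: users may add their own sensors
            if not isinstance(value, dict):
                raise ConfigError(f"key {path!r} must be a mapping")
            out[key] = {**out[key], **copy.deepcopy(value)}
            continue
        if key not in default:
            raise ConfigError(f"unknown configuration key: {path!r}")
        if isinstance(default[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"key {path!r} must be a mapping")
            out[key] = _merge_checked(default[key], value, prefix=f"{path}.")
        else:
            out[key] = copy.deepcopy(value)
    return out


@dataclass
class SystemConfig:
    """Validated configuration with typed accessors for each module."""

    raw: dict

    def sensor(self, name: str | None = None) -> SensorSpec:
        name = name or self.raw["assembly"]["sensor"]
        catalog = self.raw["sensor_catalog"]
        if name not in catalog:
            raise ConfigError(f"assembly.sensor {name!r} not in sensor_catalog")
        entry = catalog[name]
        return SensorSpec(name, entry["vsr_h"], entry["vsr_v"],
                          entry["vss_h"], entry["vss_v"])

    def assembly(self) -> OpticalAssembly:
        return OpticalAssembly(self.sensor(), LensSpec(self.raw["assembly"]["f_mm"]))

    def rig(self) -> StereoRig:
        r = self.raw["rig"]
        return StereoRig(
            baseline_m=r["baseline"],
            vsr_axis=r["vsr_axis"],
            fov_axis_deg=r["fov_axis_deg"],
            tilt_alpha_deg=r["tilt_alpha_deg"],
        )

    def detection_params(self) -> DetectionParams:
        return DetectionParams(**self.raw["detection"])

    def cnn_config(self) -> CnnConfig:
        return CnnConfig(**self.raw["cnn"])

    def boundaries(self) -> SizeClassBoundaries:
        c = self.raw["classes"]
        return SizeClassBoundaries(
            wingspan=tuple(c["wingspan"]), height=tuple(c["height"]),
            area=tuple(c["area"]),
        )

    def policy(self) -> ActionPolicy:
        p = self.raw["policy"]
        return ActionPolicy(strobe=dict(p["strobe"]), audio=dict(p["audio"]),
                            turbine_stop=dict(p["turbine_stop"]))

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def validate(self) -> "SystemConfig":
        for section, key in _REQUIRED:
            if self.raw.get(section, {}).get(key) is None:
                raise ConfigError(f"missing required key: {section}.{key!r}")
        # instantiating each typed object runs the module-level invariants
        self.assembly()
        self.rig()
        self.detection_params()
        self.cnn_config()
        self.boundaries()
        self.policy()
        return self


def load_config(path: str | Path | None = None) -> SystemConfig:
    """Load and validate a YAML config; ``None`` loads the defaults."""
    if path is None:
        return SystemConfig(copy.deepcopy(DEFAULT_CONFIG)).validate()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError("config root must be a mapping")
    # the stereo geometry is safety-critical: a file that customizes the
    # rig must state the baseline explicitly rather than inherit it
    if "rig" in user and "baseline" not in user["rig"]:
        raise ConfigError("missing required key: rig.'baseline'")
    merged = _merge_checked(DEFAULT_CONFIG, user)
    return SystemConfig(merged).validate()


def save_config(cfg: SystemConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.raw, fh, sort_keys=False)
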