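"""Run configuration: JSON round-tripping with defaulting and validation.

A :class:`RunConfig` bundles every knob of the pipeline — scene, motion,
colour spec, tracker, camera, gimbal, schedule.  Configs are plain JSON
with one object per section; missing sections and missing keys fall back to
package defaults, and every invariant violation is reported together with
the dotted path of the offending key.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np

from .files import atomic_write_json
from .geometry import CameraModel, GimbalModel
from .scene import MotionParams, SceneConfig
from .control import Schedule
from .tracking import ColorSpec, TrackerParams, default_red_spec

__all__ = ["ConfigError", "RunConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    """Invalid configuration; the message lists every violation found."""


def _tupleize(value):
    if isinstance(value, list):
        return tuple(_tupleize(v) for v in value)
    return value


def _build_section(cls, default, data: Optional[dict], path: str, errors: list[str]):
    if data is None:
        return default
    if not isinstance(data, dict):
        errors.append(f"{path}: expected an object")
        return default
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    for k in sorted(unknown):
        errors.append(f"{path}.{k}: unknown key")
    kwargs = {k: _tupleize(v) for k, v in data.items() if k in known}
    try:
        obj = dataclasses.replace(default, **kwargs)
    except (ValueError, TypeError):
        # construction-time validation failed; re-run the validator on an
        # unchecked instance to attribute every failure to its key
        obj = object.__new__(cls)
        for f in dataclasses.fields(cls):
            object.__setattr__(obj, f.name, kwargs.get(f.name, getattr(default, f.name)))
        for msg in obj.validate():
            errors.append(f"{path}.{msg}")
        return default
    return obj


@dataclass(frozen=True)
class RunConfig:
    """Everything a simulation or tracking run needs.

    ``homography_px_to_m`` overrides the camera model (rows of the 3x3
    pixel->floor matrix, e.g. from a calibration file); when absent the
    exact synthetic-camera homography implied by the scene is used.
    """

    scene: SceneConfig = field(default_factory=SceneConfig)
    motion: MotionParams = field(default_factory=MotionParams)
    color: ColorSpec = field(default_factory=default_red_spec)
    tracker: TrackerParams = field(default_factory=TrackerParams)
    gimbal: GimbalModel = field(default_factory=GimbalModel)
    schedule: Schedule = field(default_factory=Schedule)
    homography_px_to_m: Optional[tuple[tuple[float, float, float], ...]] = None

    def camera_model(self) -> CameraModel:
        if self.homography_px_to_m is not None:
            return CameraModel(homography=np.asarray(self.homography_px_to_m, dtype=float))
        return self.scene.camera_model()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


_SECTIONS = {
    "scene": SceneConfig,
    "motion": MotionParams,
    "color": ColorSpec,
    "tracker": TrackerParams,
    "gimbal": GimbalModel,
    "schedule": Schedule,
}


def config_from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("top level: expected a JSON object")
    errors: list[str] = []
    defaults = RunConfig()
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        kwargs[name] = _build_section(
            cls, getattr(defaults, name), data.get(name), name, errors
        )
    hom = data.get("homography_px_to_m")
    if hom is not None:
        arr = np.asarray(hom, dtype=float)
        if arr.shape != (3, 3):
            errors.append("homography_px_to_m: expected 3 rows of 3 numbers")
        elif abs(np.linalg.det(arr)) < 1e-15:
            errors.append("homography_px_to_m: matrix is singular")
        else:
            kwargs["homography_px_to_m"] = _tupleize(arr.tolist())
    unknown = set(data) - set(_SECTIONS) - {"homography_px_to_m"}
    for k in sorted(unknown):
        errors.append(f"{k}: unknown section")
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Parse, default and validate a JSON config file.

    Raises ``IOError`` when the file is missing and :class:`ConfigError`
    listing *all* invariant violations with their key paths.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"config file not found: {path}")
    with open(path) as f:
        try:
            data = json.load(f)
        except json.JSONDecodeError as e:
            raise ConfigError(f"{path}: not valid JSON ({e})") from e
    return config_from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config as JSON (atomic); ``load_config`` restores it exactly."""
    atomic_write_json(path, cfg.to_dict())
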