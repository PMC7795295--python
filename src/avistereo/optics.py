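"""Optical design calculator for a camera-based bird monitoring rig.

Everything here is ideal pinhole optics: given a vision sensor (resolution
and physical size per axis) and a lens (focal length), the module computes
fields of view, the projected pixel size of an object at distance, and
whether a sensor/lens pair can resolve a bird of given wingspan at the
required range.  The coverage requirement encodes the monitored space
around a turbine: at least ``360 / n_modules_max`` degrees of horizontal
field per module, and a vertical field wide enough to leave a dead zone of
no more than ``dead_zone_distance`` in front of blades of rotation
diameter ``blade_rotation_diameter``.

Units follow the field convention: sensor sizes and focal lengths in
millimetres, object sizes and distances in metres, angles in degrees.
All mm<->m conversions funnel through :data:`MM_PER_M`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

MM_PER_M = 1000.0

__all__ = [
    "SensorSpec",
    "LensSpec",
    "OpticalAssembly",
    "CoverageRequirement",
    "SENSOR_CATALOG",
    "compute_fov",
    "min_required_fovs",
    "image_size_of_object",
    "detectability_check",
    "build_selection_table",
]


@dataclass(frozen=True)
class SensorSpec:
    """Vision sensor: per-axis resolution [px] and physical size [mm]."""

    name: str
    vsr_h: int
    vsr_v: int
    vss_h: float
    vss_v: float

    def __post_init__(self) -> None:
        for attr in ("vsr_h", "vsr_v", "vss_h", "vss_v"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"SensorSpec.{attr} must be positive")

    @property
    def px_per_mm_h(self) -> float:
        return self.vsr_h / self.vss_h

    @property
    def px_per_mm_v(self) -> float:
        return self.vsr_v / self.vss_v


@dataclass(frozen=True)
class LensSpec:
    """Lens described by its focal length [mm]."""

    f: float

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("focal length must be positive")


@dataclass(frozen=True)
class OpticalAssembly:
    """A sensor/lens pair; the source of FoV and px<->m conversions."""

    sensor: SensorSpec
    lens: LensSpec

    @property
    def fov_h(self) -> float:
        """Horizontal field of view [deg]."""
        return compute_fov(self.sensor.vss_h, self.lens.f)

    @property
    def fov_v(self) -> float:
        """Vertical field of view [deg]."""
        return compute_fov(self.sensor.vss_v, self.lens.f)

    def px_per_m(self, distance_m: float, axis: str = "h") -> float:
        """Pixels subtended per metre of object extent at ``distance_m``."""
        if distance_m <= 0:
            raise ValueError("distance must be positive")
        ratio = self.sensor.px_per_mm_h if axis == "h" else self.sensor.px_per_mm_v
        return self.lens.f * ratio / distance_m

    def m_per_px(self, distance_m: float, axis: str = "h") -> float:
        return 1.0 / self.px_per_m(distance_m, axis)


@dataclass(frozen=True)
class CoverageRequirement:
    """Monitored-space constraints around the turbine.

    ``n_modules_max`` caps the module count (cost), ``dead_zone_distance``
    [m] is the largest tolerable blind spot in front of the blades, and
    ``blade_rotation_diameter`` [m] sizes the rotor.  ``min_detect_px_w``
    / ``min_detect_px_h`` are the rule-of-thumb minimum pixel extents for
    an object to be separable from the background (12 x 2 px).
    """

    n_modules_max: int = 10
    dead_zone_distance: float = 40.0
    blade_rotation_diameter: float = 80.0
    min_detect_px_w: int = 12
    min_detect_px_h: int = 2

    def __post_init__(self) -> None:
        if self.n_modules_max < 1:
            raise ValueError("n_modules_max must be >= 1")
        if self.dead_zone_distance < 0 or self.blade_rotation_diameter <= 0:
            raise ValueError("distances must be positive")
        if self.min_detect_px_w < 1 or self.min_detect_px_h < 1:
            raise ValueError("pixel minima must be >= 1")


#: Catalogue of the four candidate sensors considered for the rig.
SENSOR_CATALOG: dict[str, SensorSpec] = {
    "C1": SensorSpec("C1", 3280, 2464, 3.680, 2.760),  # IMX219
    "C2": SensorSpec("C2", 4056, 3040, 6.287, 4.712),  # IMX447
    "C3": SensorSpec("C3", 4208, 3120, 6.300, 5.700),  # AR1335
    "C4": SensorSpec("C4", 4912, 3684, 7.660, 4.560),  # AR1820HS
}


def compute_fov(sensor_extent_mm: float, f_mm: float) -> float:
    """Field of view [deg] of a sensor extent [mm] behind a lens of focal
    length ``f_mm`` [mm]: ``2 * arctan(extent / (2 f))``."""
    if sensor_extent_mm <= 0 or f_mm <= 0:
        raise ValueError("sensor extent and focal length must be positive")
    return math.degrees(2.0 * math.atan(sensor_extent_mm / (2.0 * f_mm)))


def min_required_fovs(req: CoverageRequirement) -> tuple[float, float]:
    """Minimum (horizontal, vertical) FoV [deg] implied by the coverage
    requirement.  Horizontal: ``360 / n_modules_max``.  Vertical:
    ``90 - arctan(E / R_B)`` with E the dead-zone distance and R_B the
    blade rotation diameter.  No rounding is applied; callers may floor.
    """
    fov_h = 360.0 / req.n_modules_max
    fov_v = 90.0 - math.degrees(
        math.atan(req.dead_zone_distance / req.blade_rotation_diameter)
    )
    return fov_h, fov_v


def image_size_of_object(
    size_m: float, distance_m: float, assembly: OpticalAssembly, axis: str = "h"
) -> float:
    """Continuous pixel extent of an object of ``size_m`` [m] seen at
    ``distance_m`` [m] on the chosen sensor axis."""
    if size_m <= 0:
        raise ValueError("object size must be positive")
    return size_m * assembly.px_per_m(distance_m, axis)


def detectability_check(
    size_w_m: float,
    size_h_m: float,
    distance_m: float,
    assembly: OpticalAssembly,
    req: CoverageRequirement | None = None,
) -> tuple[bool, bool]:
    """Whether the projected width / height meet the minimum pixel extents.

    Returns ``(width_ok, height_ok)``; an object must pass both to be
    considered detectable against the background.
    """
    req = req or CoverageRequirement()
    p_w = image_size_of_object(size_w_m, distance_m, assembly, "h")
    p_h = image_size_of_object(size_h_m, distance_m, assembly, "v")
    return p_w >= req.min_detect_px_w, p_h >= req.min_detect_px_h


def _feasible(
    assembly: OpticalAssembly,
    p_w: float,
    p_h: float,
    req: CoverageRequirement,
) -> bool:
    # The rig mounts the long (h-named) sensor axis along the vertical
    # baseline, so the larger-extent axis must clear the vertical FoV
    # bound and the other axis the horizontal one.
    min_h, min_v = min_required_fovs(req)
    fov_long = max(assembly.fov_h, assembly.fov_v)
    fov_short = min(assembly.fov_h, assembly.fov_v)
    return (
        p_w >= req.min_detect_px_w
        and p_h >= req.min_detect_px_h
        and fov_long >= math.floor(min_v)
        and fov_short >= min_h
    )


def build_selection_table(
    sensors: list[SensorSpec],
    focal_lengths: list[float],
    bird_w_m: float = 1.5,
    bird_h_m: float = 0.55,
    distance_m: float = 300.0,
    req: CoverageRequirement | None = None,
) -> pd.DataFrame:
    """Sensor/lens trade-off table: one row per (sensor, focal length).

    Columns: FoV per axis rounded to 0.1 deg, continuous projected pixel
    extents of the reference bird, and a feasibility flag combining the
    pixel minima with the coverage FoV bounds.
    """
    if not sensors or not focal_lengths:
        raise ValueError("sensor and focal length lists must be non-empty")
    req = req or CoverageRequirement()
    rows = []
    for sensor in sensors:
        for f in focal_lengths:
            asm = OpticalAssembly(sensor, LensSpec(f))
            p_w = image_size_of_object(bird_w_m, distance_m, asm, "h")
            p_h = image_size_of_object(bird_h_m, distance_m, asm, "v")
            rows.append(
                {
                    "sensor": sensor.name,
                    "f_mm": f,
                    "fov_h_deg": round(asm.fov_h, 1),
                    "fov_v_deg": round(asm.fov_v, 1),
                    "p_w_px": p_w,
                    "p_h_px": p_h,
                    "feasible": _feasible(asm, p_w, p_h, req),
                }
            )
    return pd.DataFrame(rows)
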