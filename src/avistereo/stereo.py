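"""Tilted vertical-baseline stereo model.

Two cameras are mounted one above the other on a turbine tower, separated
by a baseline ``B`` [m] and tilted back by an angle ``alpha`` (by
construction half the field of view along the baseline-aligned image
axis), so the pair looks up and out over the rotor.  An object projecting
to rows ``y_u`` (upper camera) and ``y_d`` (lower camera) on that axis
has disparity ``ydiff = y_u - y_d`` and lies at

    Db = B * VSR / (2 * ydiff * tan(FoV / 2))

from the baseline.  From the per-camera view angles ``phi`` the
horizontal distance from the tower and height above the lower camera are

    D = Db * (tan(phi_u) * sin(alpha) + cos(alpha))
    H = Db * (tan(phi_d) * cos(alpha) + sin(alpha))

Because the disparity is an integer number of pixel rows, localization
carries a quantization uncertainty, propagated in closed form (exact
differential) as symmetric half-widths: ``dDb = Db / (2 ydiff)``,
``dD = (D + B sin(alpha)) / (2 ydiff)``, ``dH = (H + B cos(alpha)) /
(2 ydiff)``.

Pixel rows are 1-based along the baseline-aligned axis and increase away
from the tilt direction, so that ``y_u - y_d >= 1`` for any physically
valid object in front of the rig.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "StereoRig",
    "StereoObservation",
    "Localization",
    "UncertaintyBounds",
    "InvalidDisparityError",
    "baseline_distance",
    "view_angle",
    "localize",
    "quantization_uncertainty",
    "expected_disparity",
    "solve_observation",
]


class InvalidDisparityError(ValueError):
    """Disparity below the 1 px floor (behind or impossibly far)."""


@dataclass(frozen=True)
class StereoRig:
    """Stereo rig parameters along the baseline-aligned image axis.

    ``tilt_alpha_deg`` defaults to half the field of view, the mounting
    the tower geometry calls for, but may be set independently.
    """

    baseline_m: float = 1.0
    vsr_axis: int = 3280
    fov_axis_deg: float = 63.0
    tilt_alpha_deg: float | None = None

    def __post_init__(self) -> None:
        if self.baseline_m <= 0:
            raise ValueError("baseline must be positive")
        if self.vsr_axis < 2:
            raise ValueError("vsr_axis must be >= 2")
        if not 0 < self.fov_axis_deg < 180:
            raise ValueError("fov_axis_deg must be in (0, 180)")
        if self.tilt_alpha_deg is not None and not 0 < self.tilt_alpha_deg < 90:
            raise ValueError("tilt_alpha_deg must be in (0, 90)")

    @property
    def alpha_deg(self) -> float:
        return (
            self.fov_axis_deg / 2.0
            if self.tilt_alpha_deg is None
            else self.tilt_alpha_deg
        )

    @property
    def alpha_rad(self) -> float:
        return math.radians(self.alpha_deg)

    @property
    def tan_half_fov(self) -> float:
        return math.tan(math.radians(self.fov_axis_deg) / 2.0)

    @property
    def rig_constant(self) -> float:
        """``Db * ydiff`` [m px]: the calibration constant of the rig."""
        return self.baseline_m * self.vsr_axis / (2.0 * self.tan_half_fov)


@dataclass(frozen=True)
class StereoObservation:
    """Paired 1-based pixel rows of one object on the baseline axis."""

    y_u: float
    y_d: float

    @property
    def ydiff(self) -> float:
        return self.y_u - self.y_d


@dataclass(frozen=True)
class Localization:
    """Object position: ``d_b`` from the baseline, ``d`` horizontal from
    the tower, ``h`` above the lower camera (all metres)."""

    d_b: float
    d: float
    h: float


@dataclass(frozen=True)
class UncertaintyBounds:
    """Symmetric +- half-widths [m] of the quantization uncertainty."""

    delta_db: float
    delta_d: float
    delta_h: float


def _check_ydiff(ydiff: float) -> None:
    if ydiff < 1:
        raise InvalidDisparityError(
            f"disparity {ydiff} px is below the 1 px floor"
        )


def baseline_distance(ydiff: float, rig: StereoRig) -> float:
    """Distance [m] from the baseline for a disparity of ``ydiff`` px."""
    _check_ydiff(ydiff)
    return rig.rig_constant / ydiff


def view_angle(y: float, rig: StereoRig) -> float:
    """View angle [deg] of image row ``y`` (1-based) relative to the
    optical axis: ``arctan((2 y / VSR - 1) * tan(FoV / 2))``.

    Zero at the optical centre ``y = VSR / 2``; half the field of view at
    the sensor edge ``y = VSR``.
    """
    if not 0 <= y <= rig.vsr_axis:
        raise ValueError(f"row {y} outside sensor [0, {rig.vsr_axis}]")
    return math.degrees(
        math.atan((2.0 * y / rig.vsr_axis - 1.0) * rig.tan_half_fov)
    )


def localize(obs: StereoObservation, rig: StereoRig) -> Localization:
    """Localize an observation: baseline distance from the disparity, then
    horizontal distance and height from the per-camera view angles."""
    d_b = baseline_distance(obs.ydiff, rig)
    a = math.radians(rig.alpha_deg)
    tan_phi_u = math.tan(math.radians(view_angle(obs.y_u, rig)))
    tan_phi_d = math.tan(math.radians(view_angle(obs.y_d, rig)))
    d = d_b * (tan_phi_u * math.sin(a) + math.cos(a))
    h = d_b * (tan_phi_d * math.cos(a) + math.sin(a))
    return Localization(d_b=d_b, d=d, h=h)


def quantization_uncertainty(
    loc: Localization, ydiff: float, rig: StereoRig
) -> UncertaintyBounds:
    """Closed-form quantization half-widths at a given localization."""
    _check_ydiff(ydiff)
    a = rig.alpha_rad
    two_ydiff = 2.0 * ydiff
    return UncertaintyBounds(
        delta_db=loc.d_b / two_ydiff,
        delta_d=(loc.d + rig.baseline_m * math.sin(a)) / two_ydiff,
        delta_h=(loc.h + rig.baseline_m * math.cos(a)) / two_ydiff,
    )


def expected_disparity(d_b: float, rig: StereoRig) -> tuple[float, int]:
    """Disparity a target at baseline distance ``d_b`` [m] produces:
    ``(continuous px, nearest-integer px clamped to >= 1)``."""
    if d_b <= 0:
        raise ValueError("d_b must be positive")
    continuous = rig.rig_constant / d_b
    return continuous, max(1, round(continuous))


def solve_observation(d: float, h: float, rig: StereoRig) -> StereoObservation:
    """Continuous image rows ``(y_u, y_d)`` at which an object at
    horizontal distance ``d`` and height ``h`` projects on the two
    cameras — the exact inverse of :func:`localize`.

    Solves the linear system obtained by eliminating ``Db = B / (tan(phi_u)
    - tan(phi_d))`` from the distance and height equations.  Serves as the
    ground-truth projection for the synthetic-scene generator.
    """
    a = rig.alpha_rad
    b_m = rig.baseline_m
    sin_a, cos_a = math.sin(a), math.cos(a)
    # unknowns: t_u = tan(phi_u), t_d = tan(phi_d)
    #   (d - B sin a) t_u - d t_d           = B cos a
    #   h t_u           - (h + B cos a) t_d = B sin a
    a11, a12, b1 = d - b_m * sin_a, -d, b_m * cos_a
    a21, a22, b2 = h, -(h + b_m * cos_a), b_m * sin_a
    det = a11 * a22 - a12 * a21
    if abs(det) < 1e-12:
        raise ValueError("degenerate geometry: position on the baseline axis")
    t_u = (b1 * a22 - a12 * b2) / det
    t_d = (a11 * b2 - b1 * a21) / det
    if t_u <= t_d:
        raise InvalidDisparityError(
            "position yields non-positive disparity (behind the rig)"
        )
    t = rig.tan_half_fov
    y_u = rig.vsr_axis / 2.0 * (t_u / t + 1.0)
    y_d = rig.vsr_axis / 2.0 * (t_d / t + 1.0)
    return StereoObservation(y_u=y_u, y_d=y_d)
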