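"""Synthetic stereo scenes with analytic ground truth.

Generates everything the test harnesses need: stereo frame pairs with
bird silhouettes at exactly known 3D positions, scripted flight paths
(including a circular drone-style orbit), labelled crop datasets for the
identification network, and the static-silhouette measurement campaign
(three silhouette sizes at 50-300 m reference distances).

Birds are rendered as filled isosceles triangles — the same shape the
size-approximation model assumes (base = wingspan, height = body
height), which keeps the ground truth analytic — oriented perpendicular
to the optical axis, as during gliding flight.  Between consecutive
frames a bird both translates slightly and flips its wing posture
(apex-up <-> apex-down), so the frame difference covers the full
silhouette footprint rather than two disconnected ghost stripes; this is
the generator's stand-in for wing-beat shape change.

World frame: tower base origin; ``distance`` is the horizontal range
from the tower, ``height`` the altitude above the lower camera, azimuth
the bearing within a module's horizontal field.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.draw import polygon as draw_polygon

from .detection import FrameImage
from .optics import OpticalAssembly, LensSpec, SENSOR_CATALOG
from .stereo import (
    InvalidDisparityError,
    StereoRig,
    baseline_distance,
    expected_disparity,
    solve_observation,
)

__all__ = [
    "WorldBird",
    "SceneConfig",
    "Projection",
    "OutOfViewError",
    "SILHOUETTE_SIZES",
    "default_assembly",
    "project_bird",
    "rasterized_observation",
    "render_stereo_frames",
    "simulate_flight",
    "generate_crop_dataset",
    "generate_silhouette_campaign",
]

#: Campaign silhouettes: class -> (wingspan m, body height m).
SILHOUETTE_SIZES = {
    "small": (0.8, 0.3),
    "medium": (1.2, 0.4),
    "large": (1.5, 0.5),
}


class OutOfViewError(ValueError):
    """The object does not project inside the camera frame."""


@dataclass(frozen=True)
class WorldBird:
    """A bird at a known 3D position relative to the tower."""

    distance: float  # horizontal range from the tower [m]
    height: float  # above the lower camera [m]
    azimuth_deg: float = 0.0
    wingspan: float = 1.5
    body_height: float = 0.5
    speed: float = 0.0  # along the baseline axis [m/s], used between frames
    heading_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if not self.wingspan > self.body_height > 0:
            raise ValueError("wingspan must exceed body height, both positive")


@dataclass(frozen=True)
class Projection:
    """Image-plane ground truth of one bird in one camera."""

    y: float  # 1-based row on the baseline-aligned axis
    x: float  # 1-based column on the transverse axis
    p_w: float  # wingspan extent [px]
    p_h: float  # body-height extent [px]
    d_b: float  # baseline distance [m]


@dataclass(frozen=True)
class SceneConfig:
    """Rendering parameters: rig + assembly, background and noise."""

    rig: StereoRig = field(default_factory=StereoRig)
    assembly: "OpticalAssembly" = None  # default set in __post_init__
    background: str = "flat"  # flat | gradient
    sky_level: int = 200
    bird_level: int = 30
    noise_sigma: float = 2.0
    seed: int = 0
    frame_shift_px: float = 3.0  # inter-frame translation along the axis

    def __post_init__(self) -> None:
        if self.assembly is None:
            object.__setattr__(self, "assembly", default_assembly())
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")

    @property
    def frame_shape(self) -> tuple[int, int]:
        # rows along the baseline-aligned (long) axis, columns transverse
        return self.rig.vsr_axis, self.assembly.sensor.vsr_v


def default_assembly() -> OpticalAssembly:
    return OpticalAssembly(SENSOR_CATALOG["C1"], LensSpec(3.0))


def project_bird(
    bird: WorldBird,
    camera: str,
    rig: StereoRig,
    assembly: OpticalAssembly,
) -> Projection:
    """Exact image-plane projection of a bird; the ground-truth oracle
    for stereo round-trips.

    Raises :class:`OutOfViewError` if the bird falls outside the frame.
    """
    if camera not in ("upper", "lower"):
        raise ValueError("camera must be 'upper' or 'lower'")
    try:
        obs = solve_observation(bird.distance, bird.height, rig)
    except InvalidDisparityError as exc:
        raise OutOfViewError(str(exc)) from exc
    y = obs.y_u if camera == "upper" else obs.y_d
    if not 1 <= y <= rig.vsr_axis:
        raise OutOfViewError(f"row {y:.1f} outside the baseline axis")
    d_b = baseline_distance(obs.ydiff, rig)
    sensor = assembly.sensor
    vsr_t = sensor.vsr_v
    half_fov_t = math.radians(assembly.fov_v) / 2.0
    if abs(math.radians(bird.azimuth_deg)) >= half_fov_t:
        raise OutOfViewError("azimuth outside the transverse field of view")
    x = vsr_t / 2.0 * (
        math.tan(math.radians(bird.azimuth_deg)) / math.tan(half_fov_t) + 1.0
    )
    # pixel extents use the horizontal sensor ratio, matching the size
    # estimator's convention, so round trips are exact
    px_per_m = assembly.lens.f * sensor.px_per_mm_h / d_b
    return Projection(
        y=y, x=x, p_w=bird.wingspan * px_per_m, p_h=bird.body_height * px_per_m,
        d_b=d_b,
    )


def _triangle_vertices(proj: Projection, apex_up: bool) -> tuple[list, list]:
    r, c = proj.y - 1.0, proj.x - 1.0
    half_w, half_h = proj.p_w / 2.0, proj.p_h / 2.0
    if apex_up:
        rows = [r - half_h, r + half_h, r + half_h]
        cols = [c, c - half_w, c + half_w]
    else:
        rows = [r + half_h, r - half_h, r - half_h]
        cols = [c, c - half_w, c + half_w]
    return rows, cols


def _triangle_rows_cols(
    proj: Projection, apex_up: bool, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices of the filled silhouette triangle in frame coords."""
    rows, cols = _triangle_vertices(proj, apex_up)
    return draw_polygon(rows, cols, shape=shape)


_SUPERSAMPLE = 4


def _triangle_coverage(
    proj: Projection, apex_up: bool, shape: tuple[int, int]
) -> tuple[slice, slice, np.ndarray]:
    """Sub-pixel coverage map of the silhouette (optical anti-aliasing).

    Rasterizes the triangle on a locally supersampled grid and block-
    averages, returning the bounding slices into the frame and the
    fractional coverage of each pixel there.
    """
    s = _SUPERSAMPLE
    rows, cols = _triangle_vertices(proj, apex_up)
    r0 = max(0, int(math.floor(min(rows))) - 1)
    r1 = min(shape[0], int(math.ceil(max(rows))) + 2)
    c0 = max(0, int(math.floor(min(cols))) - 1)
    c1 = min(shape[1], int(math.ceil(max(cols))) + 2)
    if r1 <= r0 or c1 <= c0:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0))
    hi_shape = ((r1 - r0) * s, (c1 - c0) * s)
    # pixel centre x maps to supersample centre s*x + (s-1)/2
    rr = [(r - r0) * s + (s - 1) / 2.0 for r in rows]
    cc = [(c - c0) * s + (s - 1) / 2.0 for c in cols]
    hi = np.zeros(hi_shape)
    pr, pc = draw_polygon(rr, cc, shape=hi_shape)
    hi[pr, pc] = 1.0
    cov = hi.reshape(r1 - r0, s, c1 - c0, s).mean(axis=(1, 3))
    return slice(r0, r1), slice(c0, c1), cov


def _background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    rows, cols = cfg.frame_shape
    if cfg.background == "gradient":
        col = np.linspace(cfg.sky_level - 30, cfg.sky_level + 30, rows)
        img = np.repeat(col[:, None], cols, axis=1)
    else:
        img = np.full((rows, cols), float(cfg.sky_level))
    if cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    return img


def render_stereo_frames(
    birds: list[WorldBird],
    cfg: SceneConfig,
    t: float = 0.0,
    flap_phase: int = 0,
) -> tuple[FrameImage, FrameImage]:
    """Render the (upper, lower) frames of a scene at time ``t``.

    ``flap_phase`` selects the wing posture (0: apex up, 1: apex down);
    alternating it between consecutive frames emulates wing-beat shape
    change.  Deterministic for a fixed config seed and time.
    """
    frames = []
    for camera in ("upper", "lower"):
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [cfg.seed, int(round(t * 1e6)) & 0x7FFFFFFF, camera == "upper"]
            )
        )
        img = _background(cfg, rng)
        for bird in birds:
            try:
                proj = project_bird(bird, camera, cfg.rig, cfg.assembly)
            except OutOfViewError:
                continue
            rs, cs, cov = _triangle_coverage(proj, apex_up=(flap_phase % 2 == 0),
                                             shape=cfg.frame_shape)
            img[rs, cs] = img[rs, cs] * (1.0 - cov) + cfg.bird_level * cov
        frames.append(
            FrameImage(np.clip(np.rint(img), 0, 255).astype(np.uint8), timestamp=t)
        )
    return frames[0], frames[1]


def rasterized_observation(
    bird: WorldBird, rig: StereoRig, assembly: OpticalAssembly,
    flap_phase: int = 0,
) -> tuple[float, float]:
    """Image-moment centroid rows ``(y_u, y_d)`` of the rasterized
    silhouette — the discrete measurement the detector would report,
    without rendering full frames."""
    ys = []
    for camera in ("upper", "lower"):
        proj = project_bird(bird, camera, rig, assembly)
        if not 1 <= proj.y - proj.p_h / 2 <= proj.y + proj.p_h / 2 <= rig.vsr_axis:
            raise OutOfViewError("silhouette clipped by the frame edge")
        size = int(math.ceil(max(proj.p_w, proj.p_h))) + 6
        # keep this camera's sub-pixel phase so rasterization errors do
        # not artificially cancel between the two cameras
        y_local = size / 2.0 + (proj.y - math.floor(proj.y))
        x_local = size / 2.0 + (proj.x - math.floor(proj.x))
        local = replace(proj, y=y_local, x=x_local)
        rs, cs, cov = _triangle_coverage(local, apex_up=(flap_phase % 2 == 0),
                                         shape=(size, size))
        if cov.sum() <= 0:
            raise OutOfViewError("silhouette rasterizes to zero pixels")
        # grayscale image moments of the anti-aliased silhouette: the
        # sub-pixel row measurement an intensity-weighted centroid yields
        rows = np.arange(rs.start, rs.stop, dtype=float)
        centroid_r = float((cov.sum(axis=1) * rows).sum() / cov.sum())
        ys.append(proj.y + (centroid_r - (local.y - 1.0)))
    return ys[0], ys[1]


def simulate_flight(
    path: str = "circular",
    duration: float = 10.0,
    fps: float = 4.0,
    radius: float = 143.3,
    height: float = 102.9,
    speed: float = 15.0,
    wingspan: float = 1.99,
    body_height: float = 1.03,
    radius_jitter: float = 2.5,
    height_jitter: float = 1.5,
    seed: int = 0,
    waypoints: list[tuple[float, float, float]] | None = None,
) -> list[WorldBird]:
    """Time series of positions along a scripted flight path.

    The circular default reproduces the drone validation orbit: radius
    143.3 m, height 102.9 m, 15 m/s, with Gaussian GPS-style jitter
    (sigma 2.5 m radial, 1.5 m vertical).  ``linear`` flies a straight
    pass at constant range; ``waypoint`` interpolates the given
    (distance, height, azimuth) triples.
    """
    if duration <= 0 or fps <= 0:
        raise ValueError("duration and fps must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fps))
    times = np.arange(n) / fps
    birds = []
    if path == "circular":
        omega = speed / radius  # rad/s
        for t in times:
            r = radius + rng.normal(0.0, radius_jitter)
            h = height + rng.normal(0.0, height_jitter)
            birds.append(
                WorldBird(
                    distance=max(r, 1.0), height=h,
                    azimuth_deg=math.degrees(omega * t) % 360.0 - 180.0,
                    wingspan=wingspan, body_height=body_height, speed=speed,
                )
            )
    elif path == "linear":
        for t in times:
            birds.append(
                WorldBird(
                    distance=radius, height=height,
                    azimuth_deg=-10.0 + math.degrees(speed * t / radius),
                    wingspan=wingspan, body_height=body_height, speed=speed,
                )
            )
    elif path == "waypoint":
        if not waypoints or len(waypoints) < 2:
            raise ValueError("waypoint path needs >= 2 waypoints")
        wp = np.asarray(waypoints, dtype=float)
        s = np.linspace(0, len(wp) - 1, n)
        for si in s:
            i = min(int(si), len(wp) - 2)
            frac = si - i
            d, h, az = (1 - frac) * wp[i] + frac * wp[i + 1]
            birds.append(
                WorldBird(distance=d, height=h, azimuth_deg=az,
                          wingspan=wingspan, body_height=body_height, speed=speed)
            )
    else:
        raise ValueError(f"unknown path type {path!r}")
    return birds


# ---------------------------------------------------------------------------
# crop dataset

def _sky_patch(rng, size):
    level = rng.uniform(160, 230)
    img = np.full((size, size), level)
    img += rng.normal(0, rng.uniform(1.0, 3.0), size=img.shape)
    return img


def _draw_bird_crop(rng, size):
    img = _sky_patch(rng, size)
    scale = size / 100.0
    p_w = rng.uniform(20, 70) * scale
    p_h = p_w * rng.uniform(0.25, 0.5)
    angle = rng.uniform(0, 2 * math.pi)
    cx = size / 2 + rng.uniform(-8, 8) * scale
    cy = size / 2 + rng.uniform(-8, 8) * scale
    base = np.array(
        [[-p_w / 2, p_h / 2], [p_w / 2, p_h / 2], [0.0, -p_h / 2]]
    )
    rot = np.array(
        [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
    )
    pts = base @ rot.T + [cx, cy]
    rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=img.shape)
    img[rr, cc] = rng.uniform(15, 80)
    return img


def _draw_insect_crop(rng, size):
    img = _sky_patch(rng, size)
    n_dots = rng.integers(1, 4)
    for _ in range(n_dots):
        margin = max(4, size // 10)
        cx, cy = rng.uniform(margin, size - margin, size=2)
        radius = rng.uniform(1.0, 3.0) * max(0.5, size / 100.0)
        yy, xx = np.ogrid[:size, :size]
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = rng.uniform(10, 60)
    return img


def _draw_plane_crop(rng, size):
    img = _sky_patch(rng, size)
    scale = size / 100.0
    length = rng.uniform(35, 85) * scale
    width = max(1.0, rng.uniform(1.5, 3.5) * scale)
    angle = rng.uniform(0, math.pi)
    cx = size / 2 + rng.uniform(-10, 10) * scale
    cy = size / 2 + rng.uniform(-10, 10) * scale
    d = np.array([math.cos(angle), math.sin(angle)])
    n = np.array([-d[1], d[0]])
    corners = [
        [cx, cy] + d * length / 2 + n * width / 2,
        [cx, cy] + d * length / 2 - n * width / 2,
        [cx, cy] - d * length / 2 - n * width / 2,
        [cx, cy] - d * length / 2 + n * width / 2,
    ]
    pts = np.asarray(corners)
    rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=img.shape)
    img[rr, cc] = rng.uniform(60, 120)
    return img


def _draw_cloud_crop(rng, size):
    from scipy.ndimage import gaussian_filter

    img = _sky_patch(rng, size)
    blob = gaussian_filter(rng.normal(0, 1, size=(size, size)),
                           rng.uniform(8, 15) * max(0.3, size / 100.0))
    blob = blob / (np.abs(blob).max() + 1e-9)
    img += blob * rng.uniform(8, 18)
    return img


def generate_crop_dataset(
    n_birds: int, n_artifacts: int, seed: int = 0, size: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled crop dataset: triangle-silhouette birds (label 1) versus
    plane streaks, insect dots and faint cloud blobs (label 0).

    Returns ``(crops, labels)`` with crops uint8 of shape
    ``(n, size, size, 3)``, shuffled, deterministic under the seed.
    """
    if n_birds < 1 or n_artifacts < 1:
        raise ValueError("need at least one sample per class")
    rng = np.random.default_rng(seed)
    artists = (_draw_insect_crop, _draw_plane_crop, _draw_cloud_crop)
    crops, labels = [], []
    for _ in range(n_birds):
        crops.append(_draw_bird_crop(rng, size))
        labels.append(1)
    for i in range(n_artifacts):
        crops.append(artists[i % len(artists)](rng, size))
        labels.append(0)
    x = np.clip(np.rint(np.stack(crops)), 0, 255).astype(np.uint8)
    x = np.repeat(x[..., None], 3, axis=3)
    y = np.asarray(labels)
    order = rng.permutation(len(y))
    return x[order], y[order]


# ---------------------------------------------------------------------------
# silhouette campaign

@dataclass
class CampaignScene:
    """One scripted measurement scene plus its ground truth."""

    label: str
    db_ref: float
    bird: WorldBird
    upper_prev: FrameImage
    upper_curr: FrameImage
    lower_prev: FrameImage
    lower_curr: FrameImage
    truth: dict


def _bird_at_baseline_distance(
    db: float, rig: StereoRig, wingspan: float, body_height: float
) -> WorldBird:
    """World position at baseline distance ``db`` that projects near the
    optical centres of both cameras (symmetric view angles)."""
    a = rig.alpha_rad
    half = rig.baseline_m / (2.0 * db)
    d = db * (half * math.sin(a) + math.cos(a))
    h = db * (-half * math.cos(a) + math.sin(a))
    return WorldBird(distance=d, height=h, wingspan=wingspan,
                     body_height=body_height)


def generate_silhouette_campaign(
    rig: StereoRig | None = None,
    assembly: OpticalAssembly | None = None,
    distances: tuple[float, ...] = (50.0, 100.0, 150.0, 200.0, 250.0, 300.0),
    sizes: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> list[CampaignScene]:
    """The static-silhouette measurement campaign: for each silhouette
    size class and reference baseline distance, a stereo frame pair in
    which the target translates slightly and flips wing posture between
    frames so the motion detector fires.

    Optionally writes PNG frames and a JSON ground-truth sidecar per
    scene under ``out_dir``.
    """
    rig = rig or StereoRig()
    assembly = assembly or default_assembly()
    sizes = sizes or SILHOUETTE_SIZES
    scenes = []
    for label, (p_w_m, p_h_m) in sizes.items():
        for db in distances:
            bird = _bird_at_baseline_distance(db, rig, p_w_m, p_h_m)
            cfg = SceneConfig(rig=rig, assembly=assembly,
                              seed=seed + int(db) * 7 + len(label))
            # translate along the baseline axis between frames
            shift_m = cfg.frame_shift_px * db / (
                assembly.lens.f * assembly.sensor.px_per_mm_h
            )
            prev_bird = replace(bird, height=bird.height - shift_m * math.cos(rig.alpha_rad),
                                distance=bird.distance + shift_m * math.sin(rig.alpha_rad))
            u_prev, l_prev = render_stereo_frames([prev_bird], cfg, t=0.0, flap_phase=1)
            u_curr, l_curr = render_stereo_frames([bird], cfg, t=0.25, flap_phase=0)
            proj_u = project_bird(bird, "upper", rig, assembly)
            truth = {
                "label": label,
                "db_ref": db,
                "distance": bird.distance,
                "height": bird.height,
                "wingspan": p_w_m,
                "body_height": p_h_m,
                "p_w_px": proj_u.p_w,
                "p_h_px": proj_u.p_h,
                "detectable": proj_u.p_w >= 12 and proj_u.p_h >= 2,
            }
            scenes.append(
                CampaignScene(
                    label=label, db_ref=db, bird=bird,
                    upper_prev=u_prev, upper_curr=u_curr,
                    lower_prev=l_prev, lower_curr=l_curr, truth=truth,
                )
            )
    if out_dir is not None:
        _write_campaign(scenes, Path(out_dir))
    return scenes


def _write_campaign(scenes: list[CampaignScene], out_dir: Path) -> None:
    from PIL import Image

    out_dir.mkdir(parents=True, exist_ok=True)
    for scene in scenes:
        stem = f"{scene.label}_{int(scene.db_ref):03d}m"
        for name in ("upper_prev", "upper_curr", "lower_prev", "lower_curr"):
            frame: FrameImage = getattr(scene, name)
            Image.fromarray(frame.pixels).save(out_dir / f"{stem}_{name}.png")
        with open(out_dir / f"{stem}_truth.json", "w") as fh:
            json.dump(scene.truth, fh, indent=2)
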