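"""Single-camera motion detection pipeline.

Two consecutive frames are Gaussian-smoothed, subtracted, thresholded,
re-smoothed to merge the split "ghost" images a moving object leaves in a
frame difference, binarized, and labelled.  Each connected component
large enough to be a plausible bird (bounding box at least 12 x 2 px by
default) becomes a :class:`DetectionCandidate` carrying its contour,
pixel extents, contour-enclosed area (shoelace / Green formula), image-
moment centroid, and a square crop for the identification network.

Pixel coordinates are 0-based, origin top-left, x rightward (columns),
y downward (rows).  Contours are external boundaries only; interior
holes are ignored (birds are treated as filled silhouettes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, transform

__all__ = [
    "FrameImage",
    "DetectionParams",
    "DetectionCandidate",
    "shoelace_area",
    "gaussian_smooth",
    "frame_difference_mask",
    "extract_candidates",
    "crop_roi",
    "detect",
]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameImage:
    """A camera frame: uint8 pixel grid (H, W) or (H, W, 3) + timestamp."""

    pixels: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] not in (1, 3)):
            raise ValueError("pixels must be (H, W) or (H, W, {1,3})")
        if px.shape[0] <= 0 or px.shape[1] <= 0:
            raise ValueError("frame dimensions must be positive")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def gray(self) -> np.ndarray:
        """Luma-weighted grayscale view as float64."""
        px = self.pixels
        if px.ndim == 2:
            return px.astype(float)
        if px.shape[2] == 1:
            return px[..., 0].astype(float)
        return px.astype(float) @ _LUMA


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the detection pipeline (all intensities 0-255).

    ``blur_kernel``/``blur_sigma`` smooth the raw frames before
    differencing; ``diff_thresh`` rejects negligible per-pixel changes;
    ``merge_kernel``/``merge_sigma`` and ``binary_thresh`` fuse the
    two-fold ghost of a moving object into one blob.  The merge defaults
    (sigma 2, threshold 100) keep targets as thin as 4 px alive while
    closing small ghost gaps; bigger gaps need a wider merge kernel.
    """

    blur_kernel: int = 5
    blur_sigma: float = 1.5
    diff_thresh: int = 25
    merge_kernel: int = 9
    merge_sigma: float = 2.0
    binary_thresh: int = 100
    min_w: int = 12
    min_h: int = 2
    crop_size: int = 100

    def __post_init__(self) -> None:
        for k in (self.blur_kernel, self.merge_kernel):
            if k < 3 or k % 2 == 0:
                raise ValueError("blur kernels must be odd and >= 3")
        for t in (self.diff_thresh, self.binary_thresh):
            if not 0 < t < 255:
                raise ValueError("thresholds must be in (0, 255)")


@dataclass
class DetectionCandidate:
    """One moving object surviving the minimum-size filter."""

    contour: np.ndarray  # (N, 2) float array of (x, y) vertices
    p_w: int
    p_h: int
    o_s: float
    centroid: tuple[float, float]  # (xc, yc)
    crop: np.ndarray | None = None
    bbox: tuple[int, int, int, int] = (0, 0, 0, 0)  # (min_x, min_y, max_x, max_y)

    def to_dict(self) -> dict:
        return {
            "contour": np.asarray(self.contour).tolist(),
            "p_w": int(self.p_w),
            "p_h": int(self.p_h),
            "o_s": float(self.o_s),
            "centroid": [float(self.centroid[0]), float(self.centroid[1])],
            "bbox": [int(v) for v in self.bbox],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionCandidate":
        return cls(
            contour=np.asarray(d["contour"], dtype=float),
            p_w=d["p_w"],
            p_h=d["p_h"],
            o_s=d["o_s"],
            centroid=tuple(d["centroid"]),
            bbox=tuple(d.get("bbox", (0, 0, 0, 0))),
        )


def shoelace_area(vertices: np.ndarray) -> float:
    """Enclosed area of an ordered closed polygon (Green/shoelace form)."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _blur(img: np.ndarray, kernel: int, sigma: float) -> np.ndarray:
    # truncate so the discrete kernel has exactly `kernel` taps per axis
    radius = kernel // 2
    return ndimage.gaussian_filter(
        img, sigma=sigma, mode="reflect", truncate=radius / sigma
    )


def gaussian_smooth(frame: FrameImage, kernel: int = 5, sigma: float = 1.5) -> FrameImage:
    """Gaussian-smooth a frame (reflected borders, kernel size fixed)."""
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError("kernel must be odd and >= 3")
    px = frame.pixels
    if px.ndim == 3:
        out = np.stack(
            [_blur(px[..., c].astype(float), kernel, sigma) for c in range(px.shape[2])],
            axis=-1,
        )
    else:
        out = _blur(px.astype(float), kernel, sigma)
    return FrameImage(np.clip(np.rint(out), 0, 255).astype(np.uint8), frame.timestamp)


def frame_difference_mask(
    prev: FrameImage,
    curr: FrameImage,
    params: DetectionParams | None = None,
) -> np.ndarray:
    """Binary motion mask: |curr - prev| -> difference threshold ->
    Gaussian merge -> binary threshold.  Returns a bool (H, W) array."""
    params = params or DetectionParams()
    if prev.pixels.shape[:2] != curr.pixels.shape[:2]:
        raise ValueError("frame dimensions differ")
    diff = np.abs(curr.gray() - prev.gray())
    raw = np.where(diff >= params.diff_thresh, 255.0, 0.0)
    merged = _blur(raw, params.merge_kernel, params.merge_sigma)
    return merged >= params.binary_thresh


def extract_candidates(
    mask: np.ndarray,
    source: FrameImage | None = None,
    min_w: int = 12,
    min_h: int = 2,
    crop_size: int = 100,
) -> list[DetectionCandidate]:
    """Measure each connected component of a binary mask and keep those
    whose bounding box is at least ``min_w`` x ``min_h`` px.

    Centroids come from image moments of the filled component; the
    enclosed area ``o_s`` from the shoelace formula over the external
    contour polygon.  Components are 8-connected; holes are ignored.
    """
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    out: list[DetectionCandidate] = []
    for region in measure.regionprops(labels):
        min_r, min_c, max_r, max_c = region.bbox
        p_w = max_c - min_c
        p_h = max_r - min_r
        if p_w < min_w or p_h < min_h:
            continue
        yc, xc = region.centroid
        filled = region.image_filled
        padded = np.pad(filled.astype(float), 1)
        contours = measure.find_contours(padded, 0.5)
        # longest contour is the external boundary; shift back to frame coords
        ext = max(contours, key=len)
        contour_xy = np.column_stack(
            [ext[:, 1] - 1 + min_c, ext[:, 0] - 1 + min_r]
        )
        o_s = shoelace_area(contour_xy)
        cand = DetectionCandidate(
            contour=contour_xy,
            p_w=p_w,
            p_h=p_h,
            o_s=o_s,
            centroid=(xc, yc),
            bbox=(min_c, min_r, max_c, max_r),
        )
        if source is not None:
            cand.crop = crop_roi(cand, source, crop_size)
        out.append(cand)
    out.sort(key=lambda c: (c.centroid[1], c.centroid[0]))
    return out


def crop_roi(
    candidate: DetectionCandidate, source: FrameImage, crop_size: int = 100
) -> np.ndarray:
    """Square uint8 (crop_size, crop_size, 3) patch centred on the
    candidate's centroid.  Objects larger than the standard mask are
    cropped at their own size and rescaled down; off-frame regions are
    zero-padded."""
    px = source.pixels
    if px.ndim == 2:
        px = np.repeat(px[:, :, None], 3, axis=2)
    elif px.shape[2] == 1:
        px = np.repeat(px, 3, axis=2)
    side = max(crop_size, candidate.p_w, candidate.p_h)
    xc, yc = candidate.centroid
    x0 = int(round(xc)) - side // 2
    y0 = int(round(yc)) - side // 2
    patch = np.zeros((side, side, 3), dtype=np.uint8)
    sy0, sy1 = max(0, y0), min(px.shape[0], y0 + side)
    sx0, sx1 = max(0, x0), min(px.shape[1], x0 + side)
    if sy1 > sy0 and sx1 > sx0:
        patch[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = px[sy0:sy1, sx0:sx1]
    if side != crop_size:
        patch = transform.resize(
            patch, (crop_size, crop_size), order=1, anti_aliasing=True,
            preserve_range=True,
        ).astype(np.uint8)
    return patch


def detect(
    prev: FrameImage,
    curr: FrameImage,
    params: DetectionParams | None = None,
) -> list[DetectionCandidate]:
    """Full pipeline: smooth -> difference mask -> measure -> crop."""
    params = params or DetectionParams()
    prev_s = gaussian_smooth(prev, params.blur_kernel, params.blur_sigma)
    curr_s = gaussian_smooth(curr, params.blur_kernel, params.blur_sigma)
    mask = frame_difference_mask(prev_s, curr_s, params)
    return extract_candidates(
        mask, source=curr, min_w=params.min_w, min_h=params.min_h,
        crop_size=params.crop_size,
    )
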