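"""Automatic pupil extraction from retroillumination frames.

Candidate circles come from a circular Hough transform over a radius
range; the best candidate is chosen by weighted voting of contrast,
circularity and color; the boundary is refined using both RGB and HSV
information, falling back to the raw candidate disk when the refined
component is implausibly small.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2gray, rgb2hsv
from skimage.feature import canny
from skimage.filters import sobel
from skimage.morphology import disk as disk_selem
from skimage.transform import hough_circle, hough_circle_peaks

__all__ = [
    "RGBImage",
    "PupilCandidate",
    "PupilRegion",
    "hough_circle_candidates",
    "score_candidates",
    "refine_pupil_mask",
    "detect_pupil",
    "DEFAULT_VOTING_WEIGHTS",
]

MIN_IMAGE_SIDE = 64
DEFAULT_VOTING_WEIGHTS = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class RGBImage:
    """A raster frame with red/green/blue channels in [0, 255]."""

    pixels: np.ndarray
    frame_index: int | None = None
    source_id: str | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("RGBImage requires a rows x cols x 3 array")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def as_rgb_array(image) -> np.ndarray:
    px = image.pixels if isinstance(image, RGBImage) else np.asarray(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("expected an RGB image (rows x cols x 3)")
    return px


@dataclass
class PupilCandidate:
    center: tuple[int, int]  # (row, col)
    radius: float
    accumulator: float = 0.0
    contrast_score: float | None = None
    circularity_score: float | None = None
    color_score: float | None = None
    total_score: float | None = None


@dataclass
class PupilRegion:
    candidate: PupilCandidate
    mask: np.ndarray
    area: int
    used_fallback: bool = False


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def hough_circle_candidates(
    image,
    radius_range: tuple[int, int] | None = None,
    max_candidates: int = 10,
    accumulator_floor: float = 0.3,
    canny_sigma: float = 2.0,
) -> list[PupilCandidate]:
    """Circular Hough candidates ordered by accumulator response.

    ``radius_range`` defaults to 10--45% of the shorter image side.  Each
    returned candidate disk lies fully inside the image; an empty list (no
    peak above ``accumulator_floor``) is a valid outcome, not an error.
    """
    px = as_rgb_array(image)
    rows, cols = px.shape[:2]
    if rows < MIN_IMAGE_SIDE or cols < MIN_IMAGE_SIDE:
        raise ValueError(f"image must be at least {MIN_IMAGE_SIDE}px on each side")
    short = min(rows, cols)
    if radius_range is None:
        radius_range = (max(5, int(0.10 * short)), int(0.45 * short))
    rmin, rmax = radius_range
    if not (0 < rmin < rmax < short / 2):
        raise ValueError(f"invalid radius range {radius_range} for a {rows}x{cols} image")

    gray = rgb2gray(px.astype(float) / 255.0)
    edges = canny(gray, sigma=canny_sigma)
    if not edges.any():
        return []
    radii = np.arange(rmin, rmax + 1)
    hspace = hough_circle(edges, radii)
    accums, cx, cy, rads = hough_circle_peaks(
        hspace,
        radii,
        total_num_peaks=max_candidates * 4,
        min_xdistance=max(1, rmin // 2),
        min_ydistance=max(1, rmin // 2),
    )
    out: list[PupilCandidate] = []
    for a, x, y, r in zip(accums, cx, cy, rads):
        if a < accumulator_floor:
            continue
        if y - r < 0 or x - r < 0 or y + r > rows - 1 or x + r > cols - 1:
            continue
        out.append(PupilCandidate(center=(int(y), int(x)), radius=float(r), accumulator=float(a)))
        if len(out) >= max_candidates:
            break
    return out


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi - lo < 1e-12:
        return np.ones_like(values)
    return (values - lo) / (hi - lo)


def score_candidates(
    image,
    candidates: Sequence[PupilCandidate],
    weights: tuple[float, float, float] = DEFAULT_VOTING_WEIGHTS,
    boundary_samples: int = 72,
) -> list[PupilCandidate]:
    """Score candidates by weighted voting of contrast, circularity, color.

    contrast  -- |mean gray inside disk - mean gray in a surrounding annulus|,
                 min-max normalized across the frame's candidates.
    circularity -- fraction of boundary samples lying on gradient ridges.
    color     -- mean (R - max(G, B)) / 255 inside the disk, clipped to [0, 1],
                 then min-max normalized (targets the red reflex).
    Returned sorted by total score descending with a deterministic
    (row, col, radius) tie-break.
    """
    if not candidates:
        raise ValueError("score_candidates requires a non-empty candidate list")
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("voting weights must be three values summing to 1")
    px = as_rgb_array(image).astype(float)
    rows, cols = px.shape[:2]
    gray = rgb2gray(px / 255.0)
    grad = sobel(gray)
    ridge_floor = 0.5 * grad.max() if grad.max() > 0 else np.inf

    contrast_raw = np.empty(len(candidates))
    circ = np.empty(len(candidates))
    color_raw = np.empty(len(candidates))
    for i, cand in enumerate(candidates):
        (cr, cc), r = cand.center, cand.radius
        inner = _disk_mask((rows, cols), (cr, cc), r)
        annulus = _disk_mask((rows, cols), (cr, cc), 1.5 * r) & ~inner
        # disk touching the border: annulus is whatever remains in-frame
        mean_in = gray[inner].mean() if inner.any() else 0.0
        mean_out = gray[annulus].mean() if annulus.any() else mean_in
        contrast_raw[i] = abs(mean_in - mean_out)

        theta = np.linspace(0, 2 * np.pi, boundary_samples, endpoint=False)
        br = np.clip(np.rint(cr + r * np.sin(theta)).astype(int), 0, rows - 1)
        bc = np.clip(np.rint(cc + r * np.cos(theta)).astype(int), 0, cols - 1)
        circ[i] = float(np.mean(grad[br, bc] >= ridge_floor))

        redness = (px[:, :, 0] - np.maximum(px[:, :, 1], px[:, :, 2])) / 255.0
        color_raw[i] = float(np.clip(redness[inner].mean(), 0.0, 1.0))

    contrast = _minmax(contrast_raw)
    color = _minmax(color_raw)
    scored = []
    for i, cand in enumerate(candidates):
        total = float(w[0] * contrast[i] + w[1] * circ[i] + w[2] * color[i])
        scored.append(
            replace(
                cand,
                contrast_score=float(contrast[i]),
                circularity_score=float(circ[i]),
                color_score=float(color[i]),
                total_score=total,
            )
        )
    scored.sort(key=lambda c: (-c.total_score, c.center[0], c.center[1], c.radius))
    return scored


def refine_pupil_mask(
    image,
    best: PupilCandidate,
    margin: int = 5,
    redness_threshold: float = 10.0,
    saturation_threshold: float = 0.15,
    value_threshold: float = 0.20,
) -> PupilRegion:
    """Refine the candidate disk into a pupil mask using RGB + HSV cues.

    The mask is the largest 8-connected component of
    (redness >= threshold) AND (saturation/value above thresholds) within
    the candidate disk dilated by ``margin``, then morphologically closed
    and hole-filled.  Falls back to the raw candidate disk (flagged) when
    the refined component covers < 50% of the disk area.
    """
    px = as_rgb_array(image).astype(float)
    rows, cols = px.shape[:2]
    (cr, cc), r = best.center, best.radius
    region = _disk_mask((rows, cols), (cr, cc), r + margin)
    disk_raw = _disk_mask((rows, cols), (cr, cc), r)

    redness = px[:, :, 0] - np.maximum(px[:, :, 1], px[:, :, 2])
    hsv = rgb2hsv(px / 255.0)
    combined = (
        (redness >= redness_threshold)
        & (hsv[:, :, 1] >= saturation_threshold)
        & (hsv[:, :, 2] >= value_threshold)
        & region
    )

    mask = np.zeros((rows, cols), dtype=bool)
    if combined.any():
        labels, n = ndi.label(combined, structure=_EIGHT)
        sizes = ndi.sum_labels(combined, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
        mask = ndi.binary_closing(mask, structure=disk_selem(3).astype(bool))
        mask = ndi.binary_fill_holes(mask)
        mask &= region
        # closing can in principle merge fragments; keep one component
        labels, n = ndi.label(mask, structure=_EIGHT)
        if n > 1:
            sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))

    disk_area = disk_raw.sum()
    if mask.sum() < 0.5 * disk_area:
        return PupilRegion(candidate=best, mask=disk_raw, area=int(disk_raw.sum()), used_fallback=True)
    return PupilRegion(candidate=best, mask=mask, area=int(mask.sum()), used_fallback=False)


def detect_pupil(
    image,
    radius_range: tuple[int, int] | None = None,
    max_candidates: int = 10,
    weights: tuple[float, float, float] = DEFAULT_VOTING_WEIGHTS,
    margin: int = 5,
) -> PupilRegion | None:
    """Full detection chain; ``None`` when no circular candidate is found."""
    candidates = hough_circle_candidates(image, radius_range, max_candidates)
    if not candidates:
        return None
    scored = score_candidates(image, candidates, weights=weights)
    return refine_pupil_mask(image, scored[0], margin=margin)
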