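"""Vessel contrast enhancement and hysteresis segmentation inside the pupil.

The red and green channels are percentile-stretched within the pupil mask
(the blue channel carries little vessel contrast under retroillumination
and is ignored), inverted into a [0, 1] vesselness map, and segmented by
two-threshold hysteresis with small-object removal.  A tuning hook re-runs
segmentation with parameter overrides, mirroring the semi-automatic manual
verification step, and every mask records the parameters that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage as ndi

from .pupil_detection import PupilRegion, as_rgb_array

__all__ = [
    "VesselnessMap",
    "VesselMap",
    "SegmentationParams",
    "enhance_contrast",
    "hysteresis_segment",
    "tune_segmentation",
]

_EIGHT = np.ones((3, 3), dtype=bool)


class SegmentationParams(NamedTuple):
    low: float = 0.25
    high: float = 0.55
    min_object_px: int = 20


@dataclass
class VesselnessMap:
    values: np.ndarray  # [0, 1], zero outside the pupil
    pupil: PupilRegion
    degenerate: bool = False  # constant-intensity interior

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("vesselness values must be finite")
        self.values = v


@dataclass
class VesselMap:
    mask: np.ndarray
    pupil: PupilRegion
    params_used: SegmentationParams


def _stretch_channel(channel: np.ndarray, inside: np.ndarray, p_low: float, p_high: float):
    vals = channel[inside]
    lo = np.percentile(vals, p_low)
    hi = np.percentile(vals, p_high)
    if hi - lo < 1e-12:
        # percentile window collapsed (e.g. vessels cover < p_low percent);
        # fall back to the full in-pupil range before declaring degeneracy
        lo, hi = vals.min(), vals.max()
        if hi - lo < 1e-12:
            return None  # truly constant interior
    return np.clip((channel - lo) / (hi - lo), 0.0, 1.0)


def enhance_contrast(
    image,
    pupil: PupilRegion,
    p_low: float = 2.0,
    p_high: float = 98.0,
    dark_vessels: bool = True,
) -> VesselnessMap:
    """Percentile contrast stretch of red and green channels inside the pupil.

    Each channel is independently stretched between its ``p_low``/``p_high``
    percentile values computed inside the pupil mask; vesselness is
    ``1 - mean(stretched R, stretched G)`` (vessels are dark on the bright
    reflex; set ``dark_vessels=False`` for the opposite polarity).  Values
    outside the pupil are exactly zero.  A constant-intensity interior
    yields an all-zero, flagged map rather than an error.
    """
    if not (0 <= p_low < p_high <= 100):
        raise ValueError("percentiles must satisfy 0 <= p_low < p_high <= 100")
    px = as_rgb_array(image).astype(float)
    inside = pupil.mask
    if not inside.any():
        raise ValueError("pupil mask is empty")
    stretched = []
    for ch in (0, 1):  # red, green; blue ignored
        s = _stretch_channel(px[:, :, ch], inside, p_low, p_high)
        if s is not None:
            stretched.append(s)
    if not stretched:
        return VesselnessMap(values=np.zeros(px.shape[:2]), pupil=pupil, degenerate=True)
    mean_rg = np.mean(stretched, axis=0)
    vness = (1.0 - mean_rg) if dark_vessels else mean_rg
    vness = np.where(inside, vness, 0.0)
    return VesselnessMap(values=vness, pupil=pupil, degenerate=False)


def hysteresis_segment(
    vness: VesselnessMap,
    low: float = SegmentationParams().low,
    high: float = SegmentationParams().high,
    min_object_px: int = SegmentationParams().min_object_px,
) -> VesselMap:
    """Two-threshold hysteresis segmentation of a vesselness map.

    Seeds are pixels >= ``high``; a pixel >= ``low`` is kept iff it is
    8-connected (through >= ``low`` pixels) to a seed.  Components smaller
    than ``min_object_px`` are removed and the result is intersected with
    the pupil mask.
    """
    if not (0 <= low < high <= 1):
        raise ValueError(f"thresholds must satisfy 0 <= low < high <= 1, got ({low}, {high})")
    if min_object_px < 0:
        raise ValueError("min_object_px must be >= 0")
    v = vness.values
    weak = v >= low
    seeds = v >= high
    mask = np.zeros_like(weak)
    if seeds.any():
        labels, n = ndi.label(weak, structure=_EIGHT)
        keep = np.unique(labels[seeds])
        keep = keep[keep > 0]
        mask = np.isin(labels, keep)
        if min_object_px > 1:
            labels, n = ndi.label(mask, structure=_EIGHT)
            sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
            small = np.flatnonzero(sizes < min_object_px) + 1
            mask &= ~np.isin(labels, small)
    mask &= vness.pupil.mask
    return VesselMap(mask=mask, pupil=vness.pupil, params_used=SegmentationParams(low, high, min_object_px))


def tune_segmentation(vness: VesselnessMap, overrides: dict | None = None) -> VesselMap:
    """Re-run hysteresis segmentation with manual parameter overrides.

    ``overrides`` may set any subset of {low, high, min_object_px}; unknown
    keys are rejected so a typo never silently falls back to defaults.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - set(SegmentationParams._fields)
    if unknown:
        raise ValueError(f"unknown segmentation override(s): {sorted(unknown)}")
    params = SegmentationParams()._replace(**overrides)
    return hysteresis_segment(vness, *params)
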