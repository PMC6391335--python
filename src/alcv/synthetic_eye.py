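"""Synthetic retroillumination eye scenes with exact ground truth.

Renders a bright reddish pupil reflex on a darker background, dark
branching vessels of known geometry inside the pupil, optional bright
artifacts (specular blobs, mucus-like streaks), defocus blur and sensor
noise.  Every scene carries a :class:`GroundTruth` record so downstream
detection, segmentation and morphometry stages can be validated without
clinical data.  Also provides a repeated-measures cohort simulator for
exercising the mixed-effects gestational-age model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "BranchSpec",
    "SyntheticSceneSpec",
    "GroundTruth",
    "SceneValidationError",
    "make_branch_sinusoid",
    "render_scene",
    "write_scene",
    "random_scene_spec",
    "simulate_cohort",
    "DEFAULT_COHORT_FEATURES",
]


class SceneValidationError(ValueError):
    """A scene specification violates a geometric invariant."""


@dataclass(frozen=True)
class BranchSpec:
    """A single vessel branch given as a sub-pixel centerline path.

    Parameters
    ----------
    path : (N, 2) array of float
        Ordered ``(row, col)`` points, N >= 2, consecutive points distinct.
    width : float or (N,) array
        Stroke width in pixels, constant or per-point, > 0.
    nominal_tortuosity_amplitude : float
        Amplitude (pixels) of the waviness used to build the path; kept as
        metadata for tortuosity-ordering tests.
    """

    path: np.ndarray
    width: float | np.ndarray = 3.0
    nominal_tortuosity_amplitude: float = 0.0

    def __post_init__(self):
        p = np.asarray(self.path, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 2:
            raise SceneValidationError("branch path must be an (N>=2, 2) array")
        steps = np.linalg.norm(np.diff(p, axis=0), axis=1)
        if np.any(steps == 0):
            raise SceneValidationError("consecutive branch path points must be distinct")
        w = np.asarray(self.width, dtype=float)
        if np.any(w <= 0):
            raise SceneValidationError("branch width must be > 0")
        object.__setattr__(self, "path", p)

    @property
    def analytic_length(self) -> float:
        """Polyline length: sum of consecutive point distances."""
        return float(np.linalg.norm(np.diff(self.path, axis=0), axis=1).sum())

    @property
    def mean_width(self) -> float:
        return float(np.mean(self.width))


@dataclass(frozen=True)
class SyntheticSceneSpec:
    image_size: tuple[int, int] = (240, 320)
    pupil_center: tuple[float, float] = (120.0, 160.0)
    pupil_radius: float = 70.0
    pupil_reflex_color: tuple[float, float, float] = (205.0, 90.0, 60.0)
    background_color: tuple[float, float, float] = (45.0, 35.0, 35.0)
    vessel_color: tuple[float, float, float] = (70.0, 20.0, 18.0)
    vessel_tree: tuple[BranchSpec, ...] = ()
    blur_sigma: float = 0.0
    noise_sigma: float = 0.0
    artifact_count: int = 0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "vessel_tree", tuple(self.vessel_tree))
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise SceneValidationError("blur_sigma and noise_sigma must be >= 0")
        if self.artifact_count < 0:
            raise SceneValidationError("artifact_count must be >= 0")
        self.validate_geometry()

    def validate_geometry(self) -> None:
        rows, cols = self.image_size
        cr, cc = self.pupil_center
        r = self.pupil_radius
        if r <= 0:
            raise SceneValidationError("pupil_radius must be > 0")
        if cr - r < 0 or cc - r < 0 or cr + r > rows - 1 or cc + r > cols - 1:
            raise SceneValidationError(
                f"pupil disk (center=({cr}, {cc}), radius={r}) extends outside "
                f"the {rows}x{cols} image"
            )
        for i, branch in enumerate(self.vessel_tree):
            d = np.linalg.norm(branch.path - np.array([cr, cc]), axis=1)
            if np.any(d > r):
                raise SceneValidationError(
                    f"vessel branch {i} leaves the pupil disk "
                    f"(max center distance {d.max():.2f} > radius {r})"
                )


@dataclass
class GroundTruth:
    pupil_mask: np.ndarray
    vessel_mask: np.ndarray
    branch_lengths: list[float]
    branch_widths: list[float]
    n_branches: int
    density: float  # percent of pupil area covered by vessel pixels

    def to_jsonable(self) -> dict:
        return {
            "n_branches": self.n_branches,
            "branch_lengths": self.branch_lengths,
            "branch_widths": self.branch_widths,
            "density": self.density,
            "pupil_area_px": int(self.pupil_mask.sum()),
            "vessel_area_px": int(self.vessel_mask.sum()),
        }


def make_branch_sinusoid(
    start: Sequence[float],
    end: Sequence[float],
    amplitude: float,
    cycles: int,
    width: float = 3.0,
    max_spacing: float = 0.25,
) -> BranchSpec:
    """Sinusoidal branch about the start--end chord.

    ``amplitude`` is the peak perpendicular deviation in pixels; amplitude 0
    degenerates to a straight segment.  Points are sampled at most
    ``max_spacing`` pixels apart along the curve.
    """
    if amplitude < 0:
        raise SceneValidationError("amplitude must be >= 0")
    if cycles < 1:
        raise SceneValidationError("cycles must be >= 1")
    p0 = np.asarray(start, dtype=float)
    p1 = np.asarray(end, dtype=float)
    chord = p1 - p0
    chord_len = float(np.linalg.norm(chord))
    if chord_len == 0:
        raise SceneValidationError("start and end of a branch must differ")
    u = chord / chord_len
    n = np.array([-u[1], u[0]])
    # crude upper bound on arc length to pick a sample count
    arc_bound = chord_len + 4.0 * amplitude * cycles
    n_samples = max(2, int(np.ceil(arc_bound / max_spacing)) + 1)
    t = np.linspace(0.0, 1.0, n_samples)
    pts = p0[None, :] + t[:, None] * chord[None, :]
    pts = pts + (amplitude * np.sin(2 * np.pi * cycles * t))[:, None] * n[None, :]
    return BranchSpec(path=pts, width=width, nominal_tortuosity_amplitude=amplitude)


def _disk_mask(shape: tuple[int, int], center: Sequence[float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _rasterize_branch(shape: tuple[int, int], branch: BranchSpec) -> np.ndarray:
    """Stamp disks of diameter ``width`` along the path at <=0.5 px steps."""
    mask = np.zeros(shape, dtype=bool)
    p = branch.path
    widths = np.broadcast_to(np.asarray(branch.width, dtype=float), (p.shape[0],))
    # resample to guarantee <=0.5 px spacing between stamps
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n_stamps = max(2, int(np.ceil(total / 0.5)) + 1)
    si = np.linspace(0.0, total, n_stamps)
    rows = np.interp(si, s, p[:, 0])
    cols = np.interp(si, s, p[:, 1])
    ws = np.interp(si, s, widths)
    for r0, c0, w in zip(rows, cols, ws):
        rad = w / 2.0
        rlo = max(0, int(np.floor(r0 - rad)))
        rhi = min(shape[0], int(np.ceil(r0 + rad)) + 1)
        clo = max(0, int(np.floor(c0 - rad)))
        chi = min(shape[1], int(np.ceil(c0 + rad)) + 1)
        if rlo >= rhi or clo >= chi:
            continue
        rr, cc = np.ogrid[rlo:rhi, clo:chi]
        mask[rlo:rhi, clo:chi] |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
    return mask


def _draw_artifacts(img: np.ndarray, spec: SyntheticSceneSpec, rng: np.random.Generator) -> None:
    """Bright elliptical specular blobs and thin bright streaks (mucus mimic)."""
    rows, cols = spec.image_size
    cr, cc = spec.pupil_center
    for _ in range(spec.artifact_count):
        kind = rng.choice(["blob", "streak"])
        # place near the pupil so artifacts actually challenge the pipeline
        theta = rng.uniform(0, 2 * np.pi)
        rho = rng.uniform(0, 0.8) * spec.pupil_radius
        ar, ac = cr + rho * np.sin(theta), cc + rho * np.cos(theta)
        color = np.array([235.0, 225.0, 215.0]) + rng.normal(0, 5, 3)
        if kind == "blob":
            a = rng.uniform(2, 6)
            b = rng.uniform(2, 6)
            phi = rng.uniform(0, np.pi)
            rr, cc2 = np.ogrid[:rows, :cols]
            dr, dc = rr - ar, cc2 - ac
            x = dr * np.cos(phi) + dc * np.sin(phi)
            y = -dr * np.sin(phi) + dc * np.cos(phi)
            m = (x / a) ** 2 + (y / b) ** 2 <= 1.0
        else:
            length = rng.uniform(10, 30)
            phi = rng.uniform(0, 2 * np.pi)
            end = (ar + length * np.sin(phi), ac + length * np.cos(phi))
            try:
                streak = BranchSpec(
                    path=np.array([[ar, ac], list(end)]), width=rng.uniform(1.0, 2.0)
                )
            except SceneValidationError:  # pragma: no cover - degenerate draw
                continue
            m = _rasterize_branch((rows, cols), streak)
        img[m] = color
    # keep artifacts inside the frame values
    np.clip(img, 0, 255, out=img)


def render_scene(spec: SyntheticSceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render ``spec`` to a uint8 RGB image plus its ground truth.

    Rendering order: background, pupil reflex disk, dark vessels,
    artifacts, Gaussian blur, Gaussian noise; finally clipped to [0, 255].
    Bit-reproducible for a fixed spec (the seed drives artifacts + noise).
    """
    spec.validate_geometry()
    rows, cols = spec.image_size
    rng = np.random.default_rng(spec.seed)

    img = np.empty((rows, cols, 3), dtype=float)
    img[:] = np.asarray(spec.background_color, dtype=float)

    pupil_mask = _disk_mask((rows, cols), spec.pupil_center, spec.pupil_radius)
    img[pupil_mask] = np.asarray(spec.pupil_reflex_color, dtype=float)

    vessel_mask = np.zeros((rows, cols), dtype=bool)
    lengths, widths = [], []
    for branch in spec.vessel_tree:
        bm = _rasterize_branch((rows, cols), branch)
        vessel_mask |= bm
        lengths.append(branch.analytic_length)
        widths.append(branch.mean_width)
    img[vessel_mask] = np.asarray(spec.vessel_color, dtype=float)

    if spec.artifact_count:
        _draw_artifacts(img, spec, rng)

    if spec.blur_sigma > 0:
        for ch in range(3):
            img[:, :, ch] = gaussian_filter(img[:, :, ch], spec.blur_sigma)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    pupil_area = int(pupil_mask.sum())
    in_pupil = int((vessel_mask & pupil_mask).sum())
    density = 100.0 * in_pupil / pupil_area if pupil_area else 0.0
    gt = GroundTruth(
        pupil_mask=pupil_mask,
        vessel_mask=vessel_mask,
        branch_lengths=lengths,
        branch_widths=widths,
        n_branches=len(spec.vessel_tree),
        density=density,
    )
    return img, gt


def write_scene(outdir: str | Path, name: str, spec: SyntheticSceneSpec) -> tuple[Path, Path]:
    """Render and write ``<name>.png`` plus a ``<name>.gt.json`` sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img, gt = render_scene(spec)
    png = outdir / f"{name}.png"
    sidecar = outdir / f"{name}.gt.json"
    iio.imwrite(png, img)
    payload = gt.to_jsonable()
    payload.update(
        {
            "pupil_center": list(spec.pupil_center),
            "pupil_radius": spec.pupil_radius,
            "seed": spec.seed,
        }
    )
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return png, sidecar


def random_scene_spec(
    seed: int,
    image_size: tuple[int, int] = (240, 320),
    n_branches: int | None = None,
    width_range: tuple[float, float] = (2.5, 6.0),
    length_range: tuple[float, float] = (20.0, 45.0),
    amplitude_range: tuple[float, float] = (0.0, 3.0),
    blur_sigma: float = 0.0,
    noise_sigma: float = 0.0,
    artifact_count: int = 0,
) -> SyntheticSceneSpec:
    """A seeded random scene with non-overlapping radial vessel branches.

    Branches radiate outward in disjoint angular sectors so that branch
    count, length and width remain exactly recoverable from the rendered
    mask (no crossings).  Pupil center/radius are jittered per seed.
    """
    rng = np.random.default_rng(seed)
    rows, cols = image_size
    short = min(rows, cols)
    radius = rng.uniform(0.24, 0.32) * short
    cr = rows / 2 + rng.uniform(-0.05, 0.05) * rows
    cc = cols / 2 + rng.uniform(-0.05, 0.05) * cols
    if n_branches is None:
        n_branches = int(rng.integers(3, 7))
    branches = []
    theta0 = rng.uniform(0, 2 * np.pi)
    for k in range(n_branches):
        theta = theta0 + 2 * np.pi * k / max(n_branches, 1)
        width = rng.uniform(*width_range)
        amp = rng.uniform(*amplitude_range)
        r_in = 0.30 * radius
        max_len = 0.92 * radius - r_in - amp - width / 2
        length = min(rng.uniform(*length_range), max_len)
        if length < 8:
            continue
        u = np.array([np.sin(theta), np.cos(theta)])
        start = np.array([cr, cc]) + r_in * u
        end = start + length * u
        branches.append(
            make_branch_sinusoid(start, end, amplitude=amp, cycles=max(1, int(length // 15)), width=width)
        )
    return SyntheticSceneSpec(
        image_size=image_size,
        pupil_center=(cr, cc),
        pupil_radius=radius,
        vessel_tree=tuple(branches),
        blur_sigma=blur_sigma,
        noise_sigma=noise_sigma,
        artifact_count=artifact_count,
        seed=seed,
    )


DEFAULT_COHORT_FEATURES = (
    "branch_length_max",
    "branch_width_max",
    "branch_width_min",
    "branch_thickness_max",
    "branch_thickness_min",
    "density",
)


def simulate_cohort(
    n_subjects: int,
    sessions_per_subject: int,
    beta: Sequence[float],
    sigma_subject: float,
    sigma_resid: float,
    seed: int,
    feature_names: Sequence[str] = DEFAULT_COHORT_FEATURES,
) -> pd.DataFrame:
    """Simulate a repeated-measures cohort for the mixed GA model.

    Features are iid standard normal per row (documented distribution).
    ``ultrasound_ga = beta[0] + X @ beta[1:] + b_subject + eps`` with
    ``b_subject ~ N(0, sigma_subject^2)`` and ``eps ~ N(0, sigma_resid^2)``.
    """
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if sessions_per_subject < 1:
        raise ValueError("sessions_per_subject must be >= 1")
    if sigma_subject < 0 or sigma_resid < 0:
        raise ValueError("variance components must be >= 0")
    feature_names = list(feature_names)
    if beta.shape[0] != len(feature_names) + 1:
        raise ValueError(
            f"beta must have {len(feature_names) + 1} entries "
            f"(intercept + one per feature), got {beta.shape[0]}"
        )
    rng = np.random.default_rng(seed)
    n_rows = n_subjects * sessions_per_subject
    X = rng.standard_normal((n_rows, len(feature_names)))
    b = rng.normal(0.0, sigma_subject, n_subjects)
    eps = rng.normal(0.0, sigma_resid, n_rows)
    subj = np.repeat(np.arange(n_subjects), sessions_per_subject)
    sess = np.tile(np.arange(sessions_per_subject), n_subjects)
    ga = beta[0] + X @ beta[1:] + b[subj] + eps
    df = pd.DataFrame(X, columns=feature_names)
    df.insert(0, "subject_id", [f"S{i:03d}" for i in subj])
    df.insert(1, "session_id", [f"V{j}" for j in sess])
    df["ultrasound_ga"] = ga
    return df
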