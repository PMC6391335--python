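"""End-to-end session pipeline: frames -> pupil -> vessels -> features -> GA.

A "video" input is either a real container (decoded through imageio when an
ffmpeg-capable backend is available), a single still image, or a directory
of ordered frame images — the latter keeps the pipeline fully testable in
environments without video codecs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import yaml
from skimage.color import rgb2gray
from skimage.filters import sobel

from . import ga_model, vessel_morphometry, vessel_segmentation
from .ga_model import AgreementStats, GAModel, bland_altman, bland_altman_plot, identity_plot, load_model, predict_ga
from .pupil_detection import (
    DEFAULT_VOTING_WEIGHTS,
    PupilRegion,
    RGBImage,
    hough_circle_candidates,
    refine_pupil_mask,
    score_candidates,
)
from .vessel_morphometry import ALCVFeatures, ALL_FEATURE_COLUMNS, aggregate_session

log = logging.getLogger("alcv.pipeline")

IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
VIDEO_SUFFIXES = {".mp4", ".mov", ".avi", ".mkv"}

__all__ = [
    "PipelineConfig",
    "SessionRecord",
    "QCFailure",
    "extract_frames",
    "rank_frames",
    "process_frame",
    "run_session",
    "run_agreement",
]


class QCFailure(RuntimeError):
    """A session failed quality control (distinct from a crash)."""


@dataclass
class PipelineConfig:
    # pupil detection
    radius_min: int | None = None
    radius_max: int | None = None
    max_candidates: int = 10
    voting_weights: tuple[float, float, float] = DEFAULT_VOTING_WEIGHTS
    refine_margin: int = 5
    # vessel segmentation
    p_low: float = 2.0
    p_high: float = 98.0
    low: float = 0.25
    high: float = 0.55
    min_object_px: int = 20
    # morphometry
    prune_len: float = 5.0
    normalize_by_pupil_radius: bool = False
    # model / orchestration
    coefficients_path: str | None = None
    frame_stride: int = 1
    top_k: int = 3
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(payload, dict):
            raise ValueError("config file must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "voting_weights" in payload:
            payload["voting_weights"] = tuple(payload["voting_weights"])
        return cls(**payload)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["voting_weights"] = list(self.voting_weights)
        return d

    @property
    def radius_range(self) -> tuple[int, int] | None:
        if self.radius_min is None or self.radius_max is None:
            return None
        return (self.radius_min, self.radius_max)


@dataclass
class SessionRecord:
    subject_id: str
    session_id: str
    video_paths: list[str] = field(default_factory=list)
    selected_frames: list[tuple[str, int]] = field(default_factory=list)
    features: ALCVFeatures | None = None
    predicted_ga: float | None = None
    ultrasound_ga: float | None = None
    capture_age_days: float | None = None
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if (self.features is None) != (self.predicted_ga is None):
            raise ValueError("predicted_ga must be present iff features are present")

    def to_jsonable(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "session_id": self.session_id,
            "video_paths": list(self.video_paths),
            "selected_frames": [list(t) for t in self.selected_frames],
            "features": self.features.to_dict() if self.features else None,
            "predicted_ga": self.predicted_ga,
            "ultrasound_ga": self.ultrasound_ga,
            "capture_age_days": self.capture_age_days,
            "qc_flags": list(self.qc_flags),
        }


def _read_frame(path: Path) -> np.ndarray:
    px = iio.imread(path)
    if px.ndim == 2:
        px = np.stack([px] * 3, axis=-1)
    if px.shape[2] == 4:
        px = px[:, :, :3]
    return px


def extract_frames(video_path: str | Path, stride: int = 1) -> list[RGBImage]:
    """Frames at the given stride, tagged with frame_index and source_id.

    Accepts a video container, a single still, or a directory of ordered
    frame images (sorted by name).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    path = Path(video_path)
    source = str(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
        if not files:
            raise ValueError(f"frame directory {path} contains no image files")
        return [
            RGBImage(_read_frame(f), frame_index=i, source_id=source)
            for i, f in enumerate(files)
            if i % stride == 0
        ]
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in IMAGE_SUFFIXES:
        return [RGBImage(_read_frame(path), frame_index=0, source_id=source)]
    if path.suffix.lower() in VIDEO_SUFFIXES:
        try:
            frames = [
                RGBImage(np.asarray(fr), frame_index=i, source_id=source)
                for i, fr in enumerate(iio.imiter(path))
                if i % stride == 0
            ]
        except Exception as exc:  # codec/backend failure: no partial output
            raise RuntimeError(
                f"cannot decode video {path}: {exc} "
                "(install an ffmpeg backend or supply a frame directory)"
            ) from exc
        if not frames:
            raise RuntimeError(f"video {path} yielded no frames (truncated file?)")
        return frames
    raise ValueError(f"unsupported input type: {path.suffix}")


def _detect(image: RGBImage, config: PipelineConfig):
    candidates = hough_circle_candidates(
        image, config.radius_range, config.max_candidates
    )
    if not candidates:
        return None
    scored = score_candidates(image, candidates, weights=config.voting_weights)
    region = refine_pupil_mask(image, scored[0], margin=config.refine_margin)
    return region


def rank_frames(frames: Sequence[RGBImage], config: PipelineConfig | None = None):
    """Order frames by pupil-detection score x focus (gradient variance).

    Frames without a detectable pupil score 0.  Ties break on frame_index,
    so the ordering is deterministic.  Returns (frame, score, region)
    triples sorted by score descending.
    """
    if not frames:
        raise ValueError("rank_frames requires a non-empty frame list")
    config = config or PipelineConfig()
    rows = []
    for frame in frames:
        region = _detect(frame, config)
        if region is None:
            rows.append((frame, None, 0.0, 0.0))
            continue
        gray = rgb2gray(frame.pixels.astype(float) / 255.0)
        grad = sobel(gray)
        focus = float(grad[region.mask].var()) if region.mask.any() else 0.0
        rows.append((frame, region, region.candidate.total_score, focus))
    focuses = [r[3] for r in rows if r[1] is not None]
    fmin = min(focuses) if focuses else 0.0
    fmax = max(focuses) if focuses else 0.0
    out = []
    for frame, region, total, focus in rows:
        if region is None:
            out.append((frame, 0.0, None))
            continue
        fnorm = 1.0 if fmax - fmin < 1e-15 else (focus - fmin) / (fmax - fmin)
        out.append((frame, float(total * fnorm), region))
    out.sort(key=lambda t: (-t[1], t[0].frame_index if t[0].frame_index is not None else 0))
    return out


def process_frame(
    image: RGBImage, config: PipelineConfig, region: PupilRegion | None = None
) -> tuple[ALCVFeatures | None, list[str]]:
    """Run one frame through segmentation + morphometry."""
    flags: list[str] = []
    if region is None:
        region = _detect(image, config)
    if region is None:
        return None, ["no pupil detected"]
    if region.used_fallback:
        flags.append("pupil refinement fell back to candidate disk")
    vness = vessel_segmentation.enhance_contrast(image, region, config.p_low, config.p_high)
    if vness.degenerate:
        flags.append("constant-intensity pupil interior")
    vmap = vessel_segmentation.hysteresis_segment(
        vness, config.low, config.high, config.min_object_px
    )
    bset = vessel_morphometry.skeletonize_map(vmap, prune_len=config.prune_len)
    bset = vessel_morphometry.measure_branches(bset, vmap)
    feats = vessel_morphometry.compute_features(bset, vmap)
    if config.normalize_by_pupil_radius:
        r = max(region.candidate.radius, 1e-9)
        d = feats.to_dict()
        for key in (
            "branch_length_max",
            "branch_length_min",
            "branch_width_max",
            "branch_width_min",
            "branch_thickness_max",
            "branch_thickness_min",
        ):
            d[key] = d[key] / r
        feats = ALCVFeatures(**d)
        flags.append("features normalized by pupil radius")
    return feats, flags


def run_session(
    config: PipelineConfig,
    video_paths: Sequence[str | Path],
    top_k: int | None = None,
    subject_id: str = "unknown",
    session_id: str = "unknown",
    ultrasound_ga: float | None = None,
    model: GAModel | None = None,
    explicit_frames: Sequence[tuple[str, int]] | None = None,
) -> SessionRecord:
    """Process a session's videos into averaged features and a GA estimate.

    Per video the top_k ranked frames are quantified and averaged; the
    per-video features are then averaged across videos.  A session where
    no frame passes pupil detection yields a QC-failed record (flag
    "insufficient retroillumination") with no features.
    """
    if not video_paths:
        raise ValueError("run_session requires at least one video")
    top_k = config.top_k if top_k is None else top_k
    model = model or load_model(config.coefficients_path)
    explicit = {}
    if explicit_frames:
        for src, idx in explicit_frames:
            explicit.setdefault(str(src), set()).add(int(idx))

    per_video: list[ALCVFeatures] = []
    selected: list[tuple[str, int]] = []
    qc_flags: list[str] = []
    for vp in video_paths:
        frames = extract_frames(vp, stride=config.frame_stride)
        if explicit:
            wanted = explicit.get(str(vp), set())
            chosen = [(f, 1.0, None) for f in frames if f.frame_index in wanted]
        else:
            ranked = rank_frames(frames, config)
            chosen = [r for r in ranked if r[1] > 0][:top_k]
        feats_here = []
        for frame, _score, region in chosen:
            feats, flags = process_frame(frame, config, region=region)
            qc_flags.extend(flags)
            if feats is not None:
                feats_here.append(feats)
                selected.append((str(vp), int(frame.frame_index or 0)))
        if feats_here:
            per_video.append(aggregate_session(feats_here))
        else:
            qc_flags.append(f"no usable frames in {vp}")

    if not per_video:
        qc_flags.append("insufficient retroillumination")
        return SessionRecord(
            subject_id=subject_id,
            session_id=session_id,
            video_paths=[str(v) for v in video_paths],
            selected_frames=[],
            features=None,
            predicted_ga=None,
            ultrasound_ga=ultrasound_ga,
            qc_flags=sorted(set(qc_flags)),
        )

    features = aggregate_session(per_video)
    ga = predict_ga(model, features)
    return SessionRecord(
        subject_id=subject_id,
        session_id=session_id,
        video_paths=[str(v) for v in video_paths],
        selected_frames=selected,
        features=features,
        predicted_ga=ga,
        ultrasound_ga=ultrasound_ga,
        qc_flags=sorted(set(qc_flags)),
    )


def run_agreement(
    records: Sequence[SessionRecord], outdir: str | Path | None = None
) -> AgreementStats:
    """Bland--Altman agreement over records carrying both GA values."""
    usable = [
        r for r in records if r.predicted_ga is not None and r.ultrasound_ga is not None
    ]
    if len(usable) < 2:
        raise ValueError(
            f"need >= 2 records with both predicted and ultrasound GA, got {len(usable)}"
        )
    pred = [r.predicted_ga for r in usable]
    ref = [r.ultrasound_ga for r in usable]
    stats = bland_altman(pred, ref)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "agreement.json").write_text(
            json.dumps(stats.to_dict(), indent=2, sort_keys=True)
        )
        bland_altman_plot(pred, ref, outdir / "bland_altman.png")
        identity_plot(pred, ref, outdir / "identity.png")
    return stats
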