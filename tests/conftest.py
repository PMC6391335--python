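from types import SimpleNamespace

import numpy as np
import pytest

from alcv.synthetic_eye import SyntheticSceneSpec, render_scene
from alcv.vessel_segmentation import SegmentationParams, VesselMap, VesselnessMap


@pytest.fixture
def clean_scene():
    """A noiseless scene: bright red-reflex pupil disk, no vessels."""
    spec = SyntheticSceneSpec(pupil_center=(120, 160), pupil_radius=60)
    img, gt = render_scene(spec)
    return spec, img, gt


def make_vmap(mask: np.ndarray, pupil_mask: np.ndarray | None = None) -> VesselMap:
    pupil = SimpleNamespace(mask=np.ones_like(mask, dtype=bool) if pupil_mask is None else pupil_mask)
    return VesselMap(mask=np.asarray(mask, bool), pupil=pupil, params_used=SegmentationParams())


def make_vness(values: np.ndarray, pupil_mask: np.ndarray | None = None) -> VesselnessMap:
    pupil = SimpleNamespace(
        mask=np.ones(values.shape, dtype=bool) if pupil_mask is None else pupil_mask
    )
    return VesselnessMap(values=np.where(pupil.mask, values, 0.0), pupil=pupil)


def brute_force_hysteresis(values, low, high, min_object_px, pupil_mask):
    """Independent oracle: threshold + BFS flood fill + component filter."""
    from collections import deque

    R, C = values.shape
    weak = values >= low
    mask = np.zeros_like(weak)
    seen = set()
    for r0 in range(R):
        for c0 in range(C):
            if values[r0, c0] >= high and (r0, c0) not in seen:
                q = deque([(r0, c0)])
                seen.add((r0, c0))
                while q:
                    r, c = q.popleft()
                    mask[r, c] = True
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < R and 0 <= cc < C and weak[rr, cc] and (rr, cc) not in seen:
                                seen.add((rr, cc))
                                q.append((rr, cc))
    # component filter by BFS as well
    comp_seen = set()
    for r0 in range(R):
        for c0 in range(C):
            if mask[r0, c0] and (r0, c0) not in comp_seen:
                comp = []
                q = deque([(r0, c0)])
                comp_seen.add((r0, c0))
                while q:
                    r, c = q.popleft()
                    comp.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < R and 0 <= cc < C and mask[rr, cc] and (rr, cc) not in comp_seen:
                                comp_seen.add((rr, cc))
                                q.append((rr, cc))
                if len(comp) < min_object_px:
                    for p in comp:
                        mask[p] = False
    return mask & pupil_mask
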