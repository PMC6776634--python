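"""Indentation-probe localization from far-red-light saturation frames.

Far-red illumination saturates every electrode except those shadowed by the
probe, so the probe footprint appears as a connected non-saturating region.
The shadow is taken as the largest 4-connected component of non-saturating
electrodes (4-connectivity resists diagonal noise bridges) and the probe
center as its centroid rounded to the nearest electrode.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError, NoShadowError

__all__ = ["detect_shadow", "estimate_center", "select_frame", "localize_probe"]

_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def detect_shadow(frame: np.ndarray, min_region: int = 8) -> np.ndarray:
    """Largest 4-connected non-saturating component as a boolean mask.

    Isolated flipped electrodes fall below ``min_region`` and are ignored.
    """
    frame = np.asarray(frame, dtype=bool)
    labeled, n = ndimage.label(~frame, structure=_STRUCTURE_4)
    if n == 0:
        raise NoShadowError("frame is fully saturating")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_region:
        raise NoShadowError(
            f"largest non-saturating component ({int(sizes[best - 1])}) "
            f"smaller than min_region={min_region}"
        )
    return labeled == best


def estimate_center(shadow: np.ndarray) -> tuple[int, int]:
    """Centroid of the shadow, rounded to the nearest electrode.

    Exact half-integer centroids break toward the smaller row/column index.
    """
    shadow = np.asarray(shadow, dtype=bool)
    coords = np.argwhere(shadow)
    if coords.size == 0:
        raise InvalidParameterError("empty shadow set")
    centroid = coords.mean(axis=0)
    # round half toward the smaller index
    return tuple(int(np.ceil(c - 0.5)) for c in centroid)


def select_frame(frames: list[np.ndarray]) -> int:
    """Index of the frame with the most salient shadow/saturation contrast.

    The chosen frame maximizes ``n_saturating * n_non_saturating`` — the
    automated stand-in for picking the visually most contrasted time-frame.
    """
    if not frames:
        raise InvalidParameterError("no frames supplied")
    scores = []
    for f in frames:
        f = np.asarray(f, dtype=bool)
        n_sat = int(f.sum())
        scores.append(n_sat * (f.size - n_sat))
    return int(np.argmax(scores))


def localize_probe(
    frame: np.ndarray,
    min_region: int = 8,
    manual_override: tuple[int, int] | None = None,
) -> dict:
    """Shadow mask + center estimate; ``manual_override`` skips detection."""
    if manual_override is not None:
        return {"center": tuple(int(v) for v in manual_override), "shadow": None, "manual": True}
    shadow = detect_shadow(frame, min_region=min_region)
    return {"center": estimate_center(shadow), "shadow": shadow, "manual": False}
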