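"""Robustness perturbations: luminance scaling, landmark-guided black-mask
occlusion, and in-plane rotation.

Brightness levels follow the two sampling bands used in luminance
robustness experiments: a ``low`` factor drawn uniformly from [0.1, 0.8]
and a ``high`` factor from [1.2, 1.9]; pixels are multiplied and clipped to
[0, 1].  Occlusion zeroes the tight landmark box of the eyes (including
brows), nose or mouth.  Rotation is applied in-plane about the landmark
centroid, consistently to pixels and landmarks; it is a desk-scale stand-in
for out-of-plane head rotation and is labeled as such wherever it is
reported.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.transform import SimilarityTransform, warp

from .exceptions import EmptyRegionError
from .geometry import LandmarkSet68, region_box

__all__ = ["perturb_brightness", "occlude", "rotate", "BRIGHTNESS_RANGES"]

BRIGHTNESS_RANGES = {"low": (0.1, 0.8), "high": (1.2, 1.9)}


def perturb_brightness(image: np.ndarray, level: str, seed: int = 0,
                       factor: float | None = None) -> tuple[np.ndarray, float]:
    """Scale intensities by a random brightness factor and clip to [0, 1].

    ``factor`` overrides the random draw (test hook / audit replay); the
    applied factor is always returned alongside the image.
    """
    img = np.asarray(image, dtype=float)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image intensities must lie in [0, 1]")
    if factor is None:
        if level not in BRIGHTNESS_RANGES:
            raise ValueError(f"unknown level {level!r}; valid: {sorted(BRIGHTNESS_RANGES)}")
        lo, hi = BRIGHTNESS_RANGES[level]
        factor = float(np.random.default_rng(seed).uniform(lo, hi))
    return np.clip(img * factor, 0.0, 1.0), float(factor)


def occlude(image: np.ndarray, lms: LandmarkSet68, region: str,
            pad: float = 2.0) -> np.ndarray:
    """Black out the tight landmark box of ``eyes`` / ``nose`` / ``mouth``.

    Pixels outside the box are returned bit-identical; a region that is
    empty after clipping to the image is a warned no-op.
    """
    img = np.asarray(image, dtype=float).copy()
    try:
        box = region_box(lms, region, pad=pad, image_shape=img.shape[:2])
    except EmptyRegionError:
        warnings.warn(f"occlusion region {region!r} empty after clipping; image unchanged")
        return img
    r0 = max(0, int(np.floor(box.y)))
    r1 = min(img.shape[0], int(np.ceil(box.bottom)))
    c0 = max(0, int(np.floor(box.x)))
    c1 = min(img.shape[1], int(np.ceil(box.right)))
    img[r0:r1, c0:c1] = 0.0
    return img


def rotate(image: np.ndarray, lms: LandmarkSet68,
           degrees: float) -> tuple[np.ndarray, LandmarkSet68]:
    """In-plane rotation about the landmark centroid.

    The same similarity transform is applied to the pixel grid and to the
    landmark coordinates, so rotated annotations stay aligned with the
    rotated image.  Typical evaluation angles are 0, 15, 30 and 45 degrees;
    arbitrary angles are accepted.
    """
    img = np.asarray(image, dtype=float)
    if degrees == 0:
        return img.copy(), LandmarkSet68(lms.points)
    cx, cy = lms.points.mean(axis=0)
    theta = np.deg2rad(degrees)
    # rotate about (cx, cy): shift to origin, rotate, shift back
    shift_in = SimilarityTransform(translation=(-cx, -cy))
    rot = SimilarityTransform(rotation=theta)
    shift_out = SimilarityTransform(translation=(cx, cy))
    tform = SimilarityTransform(matrix=shift_out.params @ rot.params @ shift_in.params)
    out = warp(img, tform.inverse, order=1, mode="constant",
               cval=float(np.median(img)), preserve_range=True)
    return out, lms.transformed(tform.params)
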