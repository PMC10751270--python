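"""Preprocessing front-end of the AU/emotion pipeline.

A face image plus its 68 landmarks is standardized into a square
:class:`FacePatch` by a similarity transform (uniform scale + translation; no
rotation, so in-plane head rotation remains visible to downstream robustness
experiments).  Histogram-of-oriented-gradients features are then extracted
from within the landmark convex hull — pixels outside the hull are zeroed
*before* gradient computation, which creates a gradient edge at the hull
boundary; that edge is the face outline and is accepted.  Finally the HOG
vectors are compressed with PCA at a retained-variance threshold.

Defaults (patch 112 px, 8 x 8 px cells, 2 x 2 cell blocks, 8 unsigned
orientation bins, L2-Hys block normalization, 95 % retained variance) are the
conventional HOG/PCA settings and are all exposed through
:class:`PreprocessConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.feature import hog as _skimage_hog
from skimage.transform import SimilarityTransform, warp
from sklearn.decomposition import PCA as _SkPCA

from .exceptions import CompatibilityError, DegenerateDataError, EmptyRegionError
from .geometry import LandmarkSet68, convex_hull_mask

__all__ = [
    "PreprocessConfig",
    "FacePatch",
    "PCABasis",
    "align_crop",
    "hog_features",
    "fit_pca",
    "project",
    "reconstruct",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """All knobs of the patch/HOG/PCA front-end in one serializable place."""

    patch_size: int = 112
    hog_orientations: int = 8
    hog_cell: int = 8
    hog_block: int = 2
    pca_retained_variance: float = 0.95

    def __post_init__(self):
        if self.patch_size < 32:
            raise ValueError("patch_size must be >= 32")
        if self.patch_size % self.hog_cell != 0:
            raise ValueError("patch_size must be divisible by hog_cell")
        if self.hog_orientations < 2:
            raise ValueError("hog_orientations must be >= 2")
        if not 0.0 < self.pca_retained_variance <= 1.0:
            raise ValueError("pca_retained_variance must lie in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        return cls(**d)

    @property
    def hog_length(self) -> int:
        cells = self.patch_size // self.hog_cell
        blocks = cells - self.hog_block + 1
        return blocks * blocks * self.hog_block * self.hog_block * self.hog_orientations


@dataclass
class FacePatch:
    """Standardized square grayscale face crop.

    Attributes
    ----------
    pixels : (P, P) float array in [0, 1], unmasked.
    transform : (3, 3) homogeneous matrix mapping original-image ``(x, y)``
        to patch coordinates.
    landmarks : the 68 landmarks expressed in patch coordinates.
    hull_mask : (P, P) boolean mask of the landmark convex hull.
    """

    pixels: np.ndarray
    transform: np.ndarray
    landmarks: LandmarkSet68
    hull_mask: np.ndarray

    @property
    def masked_pixels(self) -> np.ndarray:
        """Pixels with everything outside the landmark hull set to 0."""
        return self.pixels * self.hull_mask

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def align_crop(image: np.ndarray, lms: LandmarkSet68, patch_size: int = 112,
               expand: float = 0.10) -> FacePatch:
    """Crop and rescale the landmark region onto a ``patch_size`` square.

    The landmark bounding box is expanded by ``expand`` (10 % by default,
    split evenly on both sides of the larger dimension, squared up), then
    mapped by a similarity transform (scale + translation only) onto the
    patch.  Landmarks and hull mask are transformed consistently.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("align_crop expects a grayscale (2-D) image")
    if patch_size < 32:
        raise ValueError("patch_size must be >= 32")
    pts = lms.points
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    side = float(max(hi - lo)) * (1.0 + expand)
    if side <= 0:
        raise EmptyRegionError("landmarks span a zero-area box")
    cx, cy = (lo + hi) / 2.0
    # does the (expanded, squared) source box touch the image at all?
    rows, cols = img.shape
    half = side / 2.0
    if cx + half < 0 or cy + half < 0 or cx - half > cols or cy - half > rows:
        raise EmptyRegionError("landmark hull lies entirely outside the image")
    scale = patch_size / side
    tx = patch_size / 2.0 - cx * scale
    ty = patch_size / 2.0 - cy * scale
    tform = SimilarityTransform(scale=scale, translation=(tx, ty))
    patch = warp(img, tform.inverse, output_shape=(patch_size, patch_size),
                 order=1, mode="constant", cval=0.0, preserve_range=True)
    new_lms = lms.transformed(tform.params)
    mask = convex_hull_mask(new_lms, (patch_size, patch_size))
    return FacePatch(pixels=patch, transform=tform.params.copy(),
                     landmarks=new_lms, hull_mask=mask)


def hog_features(patch, orientations: int = 8, cell: int = 8, block: int = 2) -> np.ndarray:
    """Unsigned-gradient HOG over the hull-masked patch.

    Accepts a :class:`FacePatch` (masked automatically) or a raw 2-D array
    (used as-is).  Output length is
    ``(cells_per_side - block + 1)^2 * block^2 * orientations``.
    """
    if isinstance(patch, FacePatch):
        img = patch.masked_pixels
    else:
        img = np.asarray(patch, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("hog_features expects a square 2-D patch")
    if img.shape[0] % cell != 0:
        raise ValueError("patch size must be divisible by the cell size")
    if orientations < 2:
        raise ValueError("orientations must be >= 2")
    return _skimage_hog(
        img,
        orientations=orientations,
        pixels_per_cell=(cell, cell),
        cells_per_block=(block, block),
        block_norm="L2-Hys",
        transform_sqrt=False,
        feature_vector=True,
    )


@dataclass
class PCABasis:
    """Fitted PCA compression: mean, orthonormal components, variance fractions."""

    mean: np.ndarray                 # (d,)
    components: np.ndarray           # (k, d), orthonormal rows
    explained_variance_ratio: np.ndarray  # (k,), non-increasing
    retained_variance: float

    @property
    def k(self) -> int:
        return self.components.shape[0]

    @property
    def d(self) -> int:
        return self.components.shape[1]


def fit_pca(feature_matrix: np.ndarray, retained_variance: float = 0.95) -> PCABasis:
    """PCA of the sample covariance; keep the smallest ``k`` whose cumulative
    explained-variance fraction reaches ``retained_variance``.

    ``retained_variance=1.0`` keeps every component with nonzero variance, so
    training rows reconstruct exactly.
    """
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("feature_matrix must be 2-D with n >= 2 rows")
    if not 0.0 < retained_variance <= 1.0:
        raise ValueError("retained_variance must lie in (0, 1]")
    if np.allclose(X.var(axis=0), 0.0):
        raise DegenerateDataError("feature matrix has zero variance; PCA undefined")
    n, d = X.shape
    full = _SkPCA(n_components=min(n, d), svd_solver="full")
    full.fit(X)
    ratios = full.explained_variance_ratio_
    if retained_variance >= 1.0:
        keep = int(np.sum(full.explained_variance_ > 1e-12 * full.explained_variance_[0]))
        keep = max(keep, 1)
    else:
        keep = int(np.searchsorted(np.cumsum(ratios), retained_variance - 1e-12)) + 1
        keep = min(keep, len(ratios))
    return PCABasis(
        mean=full.mean_.copy(),
        components=full.components_[:keep].copy(),
        explained_variance_ratio=ratios[:keep].copy(),
        retained_variance=retained_variance,
    )


def project(basis: PCABasis, features: np.ndarray) -> np.ndarray:
    """Centered projection of one vector or a matrix of rows onto the basis."""
    x = np.asarray(features, dtype=float)
    if x.shape[-1] != basis.d:
        raise CompatibilityError(
            f"feature dimension {x.shape[-1]} does not match basis dimension {basis.d}"
        )
    return (x - basis.mean) @ basis.components.T


def reconstruct(basis: PCABasis, scores: np.ndarray) -> np.ndarray:
    """Inverse of :func:`project` (lossy unless the basis is full-rank)."""
    s = np.asarray(scores, dtype=float)
    if s.shape[-1] != basis.k:
        raise CompatibilityError(
            f"score dimension {s.shape[-1]} does not match basis k {basis.k}"
        )
    return s @ basis.components + basis.mean
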