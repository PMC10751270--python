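"""Landmark, bounding-box and head-pose types plus the geometric utilities
every other stage consumes.

Coordinate conventions (used package-wide):

* pixel coordinates are 0-based, ``x`` increases rightward (columns), ``y``
  increases downward (rows);
* boxes are ``(x, y, w, h)`` with ``(x, y)`` the top-left corner;
* the pixel at row ``r``, column ``c`` has its center at ``(x=c, y=r)`` and
  a point on the hull boundary counts as inside.

The 68-point landmark scheme outlines jaw, brows, nose, eyes and mouth with a
fixed index layout (see :data:`LandmarkSet68.REGIONS`).  The interocular
distance is defined here as the distance between the two *eye-center means*
(mean of indices 36-41 vs. mean of 42-47), not the outer eye corners; the
mean is stable under per-point annotation jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .exceptions import DegenerateGeometryError, EmptyRegionError

__all__ = [
    "BoundingBox",
    "LandmarkSet68",
    "HeadPose",
    "interocular_distance",
    "convex_hull_mask",
    "region_box",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned face box ``(x, y, w, h)`` with a confidence score in [0, 1]."""

    x: float
    y: float
    w: float
    h: float
    score: float = 1.0

    def __post_init__(self):
        for name in ("x", "y", "w", "h", "score"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"BoundingBox.{name} must be finite")
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"BoundingBox requires w > 0 and h > 0, got w={self.w}, h={self.h}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"BoundingBox.score must lie in [0, 1], got {self.score}")

    @property
    def right(self) -> float:
        return self.x + self.w

    @property
    def bottom(self) -> float:
        return self.y + self.h

    @property
    def area(self) -> float:
        return self.w * self.h

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.w, self.h], dtype=float)


# index layout of the 68-point scheme
_REGIONS = {
    "jaw": tuple(range(0, 17)),
    "right_brow": tuple(range(17, 22)),
    "left_brow": tuple(range(22, 27)),
    "nose": tuple(range(27, 36)),
    "right_eye": tuple(range(36, 42)),
    "left_eye": tuple(range(42, 48)),
    "mouth": tuple(range(48, 68)),
}

# regions used for landmark-guided occlusion; "eyes" deliberately includes the
# brows since the brow-raising/lowering muscles live directly above the eyes
OCCLUSION_REGIONS = {
    "eyes": tuple(range(17, 27)) + tuple(range(36, 48)),
    "nose": tuple(range(27, 36)),
    "mouth": tuple(range(48, 68)),
}


class LandmarkSet68:
    """Ordered set of 68 ``(x, y)`` landmark coordinates.

    Parameters
    ----------
    points : array-like of shape (68, 2)
        Pixel (or normalized-frame) coordinates; must all be finite.
    """

    N_POINTS = 68
    REGIONS = _REGIONS

    def __init__(self, points):
        pts = np.asarray(points, dtype=float)
        if pts.shape != (self.N_POINTS, 2):
            raise ValueError(f"expected (68, 2) points, got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        self._points = pts.copy()
        self._points.setflags(write=False)

    @property
    def points(self) -> np.ndarray:
        """Read-only (68, 2) coordinate array."""
        return self._points

    def region_points(self, region: str) -> np.ndarray:
        """Coordinates of one named region (``jaw``, ``left_eye``, ...)."""
        if region not in self.REGIONS:
            raise ValueError(f"unknown region {region!r}; valid: {sorted(self.REGIONS)}")
        return self._points[list(self.REGIONS[region])]

    def translated(self, dx: float, dy: float) -> "LandmarkSet68":
        return LandmarkSet68(self._points + np.array([dx, dy]))

    def transformed(self, matrix: np.ndarray) -> "LandmarkSet68":
        """Apply a 3x3 homogeneous transform to all points."""
        m = np.asarray(matrix, dtype=float)
        homo = np.column_stack([self._points, np.ones(self.N_POINTS)])
        out = homo @ m.T
        return LandmarkSet68(out[:, :2] / out[:, 2:3])

    def bounding_box(self, pad: float = 0.0, score: float = 1.0) -> BoundingBox:
        lo = self._points.min(axis=0) - pad
        hi = self._points.max(axis=0) + pad
        return BoundingBox(lo[0], lo[1], hi[0] - lo[0], hi[1] - lo[1], score)

    def eye_centers(self) -> tuple[np.ndarray, np.ndarray]:
        right = self.region_points("right_eye").mean(axis=0)
        left = self.region_points("left_eye").mean(axis=0)
        return right, left

    def __eq__(self, other):
        return isinstance(other, LandmarkSet68) and np.array_equal(self._points, other._points)

    def __repr__(self):
        c = self._points.mean(axis=0)
        return f"LandmarkSet68(centroid=({c[0]:.2f}, {c[1]:.2f}))"


@dataclass(frozen=True)
class HeadPose:
    """Head orientation in degrees: pitch (x), roll (y), yaw (z)."""

    pitch: float
    roll: float
    yaw: float

    def __post_init__(self):
        for name in ("pitch", "roll", "yaw"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"HeadPose.{name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.pitch, self.roll, self.yaw], dtype=float)


def interocular_distance(lms: LandmarkSet68) -> float:
    """Euclidean distance between the two eye-center means.

    Raises
    ------
    DegenerateGeometryError
        If the two eye centers coincide (unusable annotation).
    """
    right, left = lms.eye_centers()
    d = float(np.hypot(*(left - right)))
    if d < 1e-12:
        raise DegenerateGeometryError("eye centers coincide; interocular distance undefined")
    return d


def convex_hull_mask(lms: LandmarkSet68, image_shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside (or on) the landmark hull.

    Parameters
    ----------
    image_shape : (rows, cols)
    """
    rows, cols = int(image_shape[0]), int(image_shape[1])
    if rows <= 0 or cols <= 0:
        raise ValueError(f"image_shape must be positive, got {image_shape}")
    hull = shapely.MultiPoint(lms.points).convex_hull
    if hull.geom_type != "Polygon":
        raise DegenerateGeometryError("landmarks are collinear; convex hull is degenerate")
    # clip the pixel grid to the hull's bounding box to keep the test cheap
    minx, miny, maxx, maxy = hull.bounds
    c0 = max(0, int(np.floor(minx)))
    c1 = min(cols - 1, int(np.ceil(maxx)))
    r0 = max(0, int(np.floor(miny)))
    r1 = min(rows - 1, int(np.ceil(maxy)))
    mask = np.zeros((rows, cols), dtype=bool)
    if c1 < c0 or r1 < r0:
        return mask
    xs, ys = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    # intersects == "inside or on the boundary"
    inside = shapely.intersects_xy(hull, xs.ravel(), ys.ravel()).reshape(xs.shape)
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside
    return mask


def region_box(
    lms: LandmarkSet68,
    region: str,
    pad: float = 0.0,
    image_shape: tuple[int, int] | None = None,
) -> BoundingBox:
    """Tight box around an occlusion region (``eyes`` includes brows).

    ``pad`` expands each side; when ``image_shape`` is given the box is
    clipped to the image bounds.
    """
    if region not in OCCLUSION_REGIONS:
        raise ValueError(f"unknown region {region!r}; valid: {sorted(OCCLUSION_REGIONS)}")
    if pad < 0:
        raise ValueError("pad must be non-negative")
    pts = lms.points[list(OCCLUSION_REGIONS[region])]
    x0, y0 = pts.min(axis=0) - pad
    x1, y1 = pts.max(axis=0) + pad
    if image_shape is not None:
        rows, cols = image_shape
        x0, y0 = max(x0, 0.0), max(y0, 0.0)
        x1, y1 = min(x1, float(cols)), min(y1, float(rows))
        if x1 <= x0 or y1 <= y0:
            raise EmptyRegionError(f"region {region!r} is empty after clipping to the image")
    return BoundingBox(x0, y0, x1 - x0, y1 - y0)
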