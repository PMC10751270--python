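"""AU -> landmark generative face model.

The model is linear: a neutral 68-point template ``T`` (in a normalized frame
with centroid at the origin and interocular distance 1) plus a deformation
matrix ``W`` of shape (136, K) mapping a K-length action-unit activation
vector ``a`` (each entry expected in [0, 1]) to landmark displacements::

    landmarks(a) = T + reshape(W @ a, (68, 2))

Linearity buys three properties the visualization tools rely on: zero
activation reproduces the template exactly, deformations are additive, and
morphs between two expressions are straight-line trajectories in landmark
space.  Fitting uses ordinary least squares per output coordinate; partial
least squares can be swapped in by fitting externally and constructing an
:class:`AUFaceModel` directly.

The default model shipped with the package (:func:`default_face_model`)
carries a hand-designed template and per-AU deformation fields for the 12
detection AUs (optionally a few extras).  Its deformation directions follow
the FACS muscle semantics (AU1 raises the inner brows, AU12 pulls the mouth
corners up and out, AU26 drops the jaw, ...); magnitudes are in interocular
units and are a stylization, not a claim about any specific dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .exceptions import CollinearityError
from .geometry import LandmarkSet68, interocular_distance
from .rendering import normalized_to_canvas, render_face

__all__ = [
    "AUFaceModel",
    "MuscleHeatmapSpec",
    "fit_face_model",
    "generate_landmarks",
    "plot_face",
    "animate_face",
    "default_face_model",
    "default_heatmap_spec",
    "normalize_shapes",
    "DETECTION_AUS",
]

DETECTION_AUS = (
    "AU01", "AU02", "AU04", "AU05", "AU06", "AU09",
    "AU12", "AU15", "AU17", "AU20", "AU25", "AU26",
)

EXTRA_AUS = ("AU07", "AU10", "AU14", "AU23")


@dataclass
class AUFaceModel:
    """Neutral template plus linear AU->displacement map."""

    template: LandmarkSet68
    W: np.ndarray                      # (136, K)
    au_names: tuple[str, ...]
    activation_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        self.au_names = tuple(self.au_names)
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (136, len(self.au_names)):
            raise ValueError(
                f"W must be (136, {len(self.au_names)}), got {self.W.shape}"
            )

    @property
    def K(self) -> int:
        return len(self.au_names)

    def au_vector(self, active: dict[str, float]) -> np.ndarray:
        """Build an activation vector from a name -> intensity mapping."""
        a = np.zeros(self.K)
        for name, v in active.items():
            if name not in self.au_names:
                raise ValueError(f"unknown AU {name!r}")
            a[self.au_names.index(name)] = v
        return a


@dataclass
class MuscleHeatmapSpec:
    """Per-AU anchor points (landmark index + offset, in interocular units)
    and a radial falloff scale, used to shade approximate muscle locations."""

    anchors: dict[str, list[tuple[int, float, float]]]
    sigma: float = 0.18

    def validate(self, au_names) -> None:
        missing = [a for a in au_names if not self.anchors.get(a)]
        if missing:
            raise ValueError(f"heatmap spec lacks anchors for {missing}")


def normalize_shapes(landmark_matrix: np.ndarray) -> np.ndarray:
    """Translate each 136-vector shape row to zero centroid and scale its
    interocular distance to 1 (Procrustes without rotation)."""
    L = np.asarray(landmark_matrix, dtype=float)
    out = np.empty_like(L)
    for i, row in enumerate(L):
        pts = row.reshape(68, 2)
        pts = pts - pts.mean(axis=0)
        d = interocular_distance(LandmarkSet68(pts))
        out[i] = (pts / d).ravel()
    return out


def fit_face_model(au_matrix: np.ndarray, landmark_matrix: np.ndarray,
                   au_names=None, template_policy: str = "auto") -> AUFaceModel:
    """Fit template + deformation matrix by per-coordinate OLS.

    Parameters
    ----------
    au_matrix : (n, K) activations; must be full column rank.
    landmark_matrix : (n, 136) shape rows, already normalized
        (see :func:`normalize_shapes`).
    template_policy : "auto" uses the mean shape of all-zero-AU rows when
        such rows exist, else the intercept of the regression.
    """
    A = np.asarray(au_matrix, dtype=float)
    L = np.asarray(landmark_matrix, dtype=float)
    if A.ndim != 2 or L.ndim != 2 or A.shape[0] != L.shape[0]:
        raise ValueError("au_matrix and landmark_matrix must share n rows")
    n, K = A.shape
    if L.shape[1] != 136:
        raise ValueError("landmark_matrix rows must have length 136")
    if n <= K:
        raise ValueError(f"need n > K ({n} <= {K})")
    if au_names is None:
        au_names = tuple(f"AU{i:02d}" for i in range(1, K + 1))
    au_names = tuple(au_names)

    rank = np.linalg.matrix_rank(A)
    if rank < K:
        _, _, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
        dependent = sorted(au_names[j] for j in piv[rank:])
        raise CollinearityError(
            f"AU activation matrix is rank deficient; dependent columns: {dependent}",
            columns=dependent,
        )

    zero_rows = np.all(A == 0.0, axis=1)
    if template_policy == "auto" and zero_rows.any():
        template = L[zero_rows].mean(axis=0)
        beta, *_ = np.linalg.lstsq(A, L - template, rcond=None)
        W = beta.T
    else:
        X = np.column_stack([np.ones(n), A])
        beta, *_ = np.linalg.lstsq(X, L, rcond=None)
        template = beta[0]
        W = beta[1:].T
    return AUFaceModel(template=LandmarkSet68(template.reshape(68, 2)),
                       W=W, au_names=au_names)


def generate_landmarks(model: AUFaceModel, au) -> LandmarkSet68:
    """Deform the template by an activation vector: ``T + reshape(W @ au)``."""
    a = np.asarray(au, dtype=float).ravel()
    if a.shape[0] != model.K:
        raise ValueError(f"expected activation vector of length {model.K}, got {a.shape[0]}")
    if not np.all(np.isfinite(a)):
        raise ValueError("activation vector must be finite")
    disp = (model.W @ a).reshape(68, 2)
    return LandmarkSet68(model.template.points + disp)


def _heat_field(model: AUFaceModel, spec: MuscleHeatmapSpec, au: np.ndarray,
                canvas_size: int) -> np.ndarray:
    """Sum of radial Gaussians, one per active AU anchor, in [0, 1]."""
    heat = np.zeros((canvas_size, canvas_size))
    ys, xs = np.mgrid[0:canvas_size, 0:canvas_size]
    scale = canvas_size / 3.4
    for name, act in zip(model.au_names, au):
        if act == 0 or name not in spec.anchors:
            continue
        for (idx, dx, dy) in spec.anchors[name]:
            anchor = model.template.points[idx] + np.array([dx, dy])
            cx, cy = normalized_to_canvas(anchor[None, :], canvas_size)[0]
            r2 = (xs - cx) ** 2 + (ys - cy) ** 2
            s = spec.sigma * scale
            heat += float(np.clip(abs(act), 0, 1)) * np.exp(-r2 / (2 * s * s))
    heat[heat < 1e-4] = 0.0  # compact support: far pixels stay untouched
    return np.clip(heat, 0.0, 1.0)


def plot_face(model: AUFaceModel, au, heatmap: MuscleHeatmapSpec | None = None,
              canvas_size: int = 256) -> np.ndarray:
    """Render the face implied by an activation vector.

    Returns an RGB float array of shape ``(canvas_size, canvas_size, 3)``.
    With a heatmap spec, muscle activation is shaded in red at the anchor
    locations; pixels outside the heatmap support are identical to the plain
    render.  Same inputs always give identical pixels.
    """
    if canvas_size <= 0:
        raise ValueError("canvas_size must be positive")
    a = _resolve_au(model, au)
    lms = generate_landmarks(model, a)
    gray = render_face(normalized_to_canvas(lms.points, canvas_size), canvas_size)
    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    if heatmap is not None:
        heatmap.validate(model.au_names)
        heat = _heat_field(model, heatmap, a, canvas_size)
        rgb[:, :, 0] = np.clip(rgb[:, :, 0] + 0.8 * heat, 0, 1)
        rgb[:, :, 1] = np.clip(rgb[:, :, 1] - 0.3 * heat, 0, 1)
        rgb[:, :, 2] = np.clip(rgb[:, :, 2] - 0.3 * heat, 0, 1)
    return rgb


def animate_face(model: AUFaceModel, start_au, end_au, n_frames: int,
                 heatmap: MuscleHeatmapSpec | None = None,
                 canvas_size: int = 256) -> list[np.ndarray]:
    """Linear morph between two activation vectors, rendered frame by frame.

    Frame ``i`` shows ``start + (i / (n_frames - 1)) * (end - start)``; the
    endpoints are exactly the static renders of start and end.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    a0 = _resolve_au(model, start_au)
    a1 = _resolve_au(model, end_au)
    frames = []
    for i in range(n_frames):
        t = i / (n_frames - 1)
        frames.append(plot_face(model, a0 + t * (a1 - a0), heatmap, canvas_size))
    return frames


def _resolve_au(model: AUFaceModel, au) -> np.ndarray:
    if isinstance(au, str):
        if au == "neutral":
            return np.zeros(model.K)
        raise ValueError(f"unknown named expression {au!r}")
    if isinstance(au, dict):
        return model.au_vector(au)
    a = np.asarray(au, dtype=float).ravel()
    if a.shape[0] != model.K:
        raise ValueError(f"expected activation vector of length {model.K}")
    return a


# ----------------------------------------------------------------------------
# default template and deformation fields
# ----------------------------------------------------------------------------

def _build_template() -> np.ndarray:
    """Hand-laid-out neutral face in interocular units (x right, y down)."""
    pts = np.zeros((68, 2))
    # jaw 0-16: lower half of an ellipse from right temple to left temple
    phi = np.pi + np.arange(17) * (np.pi / 16.0)
    pts[0:17, 0] = 1.15 * np.cos(phi)
    pts[0:17, 1] = 0.35 + 1.25 * np.sin(phi) * -1.0  # sin<0 on (pi, 2pi) -> chin below
    # brows 17-21 (right), 22-26 (left)
    bx = np.array([0.85, 0.70, 0.55, 0.40, 0.25])
    by = np.array([-0.22, -0.27, -0.29, -0.27, -0.24])
    pts[17:22, 0] = -bx
    pts[17:22, 1] = by
    pts[22:27, 0] = bx[::-1]
    pts[22:27, 1] = by[::-1]
    # nose bridge 27-30 and nostril line 31-35
    pts[27:31] = [(0.0, -0.05), (0.0, 0.12), (0.0, 0.28), (0.0, 0.45)]
    pts[31:36] = [(-0.16, 0.53), (-0.08, 0.56), (0.0, 0.58), (0.08, 0.56), (0.16, 0.53)]
    # eyes 36-41 (right), 42-47 (left); eye centers at (-0.5, 0) and (0.5, 0)
    pts[36:42] = [(-0.68, 0.0), (-0.59, -0.06), (-0.41, -0.06),
                  (-0.32, 0.0), (-0.41, 0.06), (-0.59, 0.06)]
    pts[42:48] = [(0.32, 0.0), (0.41, -0.06), (0.59, -0.06),
                  (0.68, 0.0), (0.59, 0.06), (0.41, 0.06)]
    # mouth: outer 48-59, inner 60-67
    pts[48:60] = [(-0.42, 0.95), (-0.28, 0.88), (-0.12, 0.84), (0.0, 0.86),
                  (0.12, 0.84), (0.28, 0.88), (0.42, 0.95), (0.28, 1.05),
                  (0.12, 1.10), (0.0, 1.11), (-0.12, 1.10), (-0.28, 1.05)]
    pts[60:68] = [(-0.34, 0.95), (-0.12, 0.92), (0.0, 0.93), (0.12, 0.92),
                  (0.34, 0.95), (0.12, 1.00), (0.0, 1.01), (-0.12, 1.00)]
    return pts


def _build_deformations(au_names) -> np.ndarray:
    """Per-AU displacement fields, in interocular units per unit activation."""
    W = np.zeros((136, len(au_names)))

    def add(au, idx, dx=0.0, dy=0.0):
        j = au_names.index(au)
        W[2 * idx, j] += dx
        W[2 * idx + 1, j] += dy

    # AU01 inner brow raiser
    for i, g in [(21, 1.0), (20, 0.7), (19, 0.35), (22, 1.0), (23, 0.7), (24, 0.35)]:
        add("AU01", i, dy=-0.21 * g)
    # AU02 outer brow raiser
    for i, g in [(17, 1.0), (18, 0.65), (26, 1.0), (25, 0.65)]:
        add("AU02", i, dy=-0.16 * g)
    # AU04 brow lowerer: brows down and pulled toward the midline
    for i in range(17, 22):
        g = 0.5 + 0.5 * (i - 17) / 4.0          # inner end strongest
        add("AU04", i, dx=+0.08 * g, dy=+0.17 * g)
    for i in range(22, 27):
        g = 0.5 + 0.5 * (26 - i) / 4.0
        add("AU04", i, dx=-0.08 * g, dy=+0.17 * g)
    # AU05 upper lid raiser
    for i in (37, 38, 43, 44):
        add("AU05", i, dy=-0.09)
    # AU06 cheek raiser: lower lids pushed up, slight squeeze of outer corners
    for i in (40, 41, 46, 47):
        add("AU06", i, dy=-0.08)
    for i, s in [(36, +1), (45, -1)]:
        add("AU06", i, dx=0.02 * s)
    # AU09 nose wrinkler: nose drawn up, nostrils flare, inner brows dip
    for i in range(30, 36):
        add("AU09", i, dy=-0.10)
    add("AU09", 31, dx=-0.05)
    add("AU09", 35, dx=+0.05)
    for i in (21, 22):
        add("AU09", i, dy=+0.06)
    # AU12 lip corner puller (smile): corners out and up
    for i, s, g in [(48, -1, 1.0), (54, +1, 1.0), (49, -1, 0.5), (53, +1, 0.5),
                    (59, -1, 0.5), (55, +1, 0.5), (60, -1, 0.7), (64, +1, 0.7)]:
        add("AU12", i, dx=0.16 * s * g, dy=-0.13 * g)
    # AU15 lip corner depressor: corners down, slightly out
    for i, s, g in [(48, -1, 1.0), (54, +1, 1.0), (60, -1, 0.7), (64, +1, 0.7),
                    (59, -1, 0.5), (55, +1, 0.5)]:
        add("AU15", i, dx=0.03 * s * g, dy=+0.15 * g)
    # AU17 chin raiser: chin and lower lip pushed up
    for i, g in [(8, 1.0), (7, 0.6), (9, 0.6)]:
        add("AU17", i, dy=-0.13 * g)
    for i in range(55, 60):
        add("AU17", i, dy=-0.05)
    for i in (65, 66, 67):
        add("AU17", i, dy=-0.04)
    # AU20 lip stretcher: corners pulled straight outward
    for i, s, g in [(48, -1, 1.0), (54, +1, 1.0), (49, -1, 0.55), (53, +1, 0.55),
                    (59, -1, 0.55), (55, +1, 0.55), (60, -1, 0.75), (64, +1, 0.75)]:
        add("AU20", i, dx=0.19 * s * g, dy=+0.02 * g)
    # stretching thins the lips
    for i in (50, 51, 52):
        add("AU20", i, dy=+0.02)
    for i in (56, 57, 58):
        add("AU20", i, dy=-0.02)
    # AU25 lips part: inner lips separate (opening widens, jaw stays)
    for i in (61, 62, 63):
        add("AU25", i, dy=-0.08)
    for i in (65, 66, 67):
        add("AU25", i, dy=+0.14)
    for i in range(55, 60):
        add("AU25", i, dy=+0.07)
    # AU26 jaw drop: jaw and lower lip descend
    for i, g in [(8, 1.0), (7, 0.85), (9, 0.85), (6, 0.55), (10, 0.55), (5, 0.3), (11, 0.3)]:
        add("AU26", i, dy=+0.19 * g)
    for i in range(55, 60):
        add("AU26", i, dy=+0.13)
    for i in (65, 66, 67):
        add("AU26", i, dy=+0.14)
    for i, s in [(48, 0), (54, 0)]:
        add("AU26", i, dy=+0.05)

    if "AU07" in au_names:  # lid tightener: lids squeeze together
        for i in (37, 38, 43, 44):
            add("AU07", i, dy=+0.03)
        for i in (40, 41, 46, 47):
            add("AU07", i, dy=-0.03)
    if "AU10" in au_names:  # upper lip raiser
        for i in range(49, 54):
            add("AU10", i, dy=-0.06)
        for i in (61, 62, 63):
            add("AU10", i, dy=-0.05)
    if "AU14" in au_names:  # dimpler: corners pressed inward slightly
        add("AU14", 48, dx=+0.05)
        add("AU14", 54, dx=-0.05)
    if "AU23" in au_names:  # lip tightener: lips compress toward center
        for i in (50, 51, 52):
            add("AU23", i, dy=+0.03)
        for i in (56, 57, 58):
            add("AU23", i, dy=-0.03)
        add("AU23", 48, dx=+0.04)
        add("AU23", 54, dx=-0.04)
    return W


def default_face_model(extended: bool = False) -> AUFaceModel:
    """The packaged stylized face model over the 12 detection AUs
    (plus AU07/AU10/AU14/AU23 when ``extended=True``)."""
    names = DETECTION_AUS + (EXTRA_AUS if extended else ())
    pts = _build_template()
    pts = pts - pts.mean(axis=0)  # centroid at origin; interocular stays 1
    return AUFaceModel(template=LandmarkSet68(pts),
                       W=_build_deformations(list(names)),
                       au_names=names)


def default_heatmap_spec() -> MuscleHeatmapSpec:
    """Hand-curated muscle anchor table (approximate locations only)."""
    anchors = {
        "AU01": [(21, 0.0, -0.12), (22, 0.0, -0.12)],
        "AU02": [(17, 0.0, -0.12), (26, 0.0, -0.12)],
        "AU04": [(21, 0.08, 0.05), (22, -0.08, 0.05)],
        "AU05": [(37, 0.05, -0.05), (44, -0.05, -0.05)],
        "AU06": [(41, 0.0, 0.18), (46, 0.0, 0.18)],
        "AU09": [(27, 0.0, 0.0)],
        "AU12": [(48, -0.08, 0.0), (54, 0.08, 0.0)],
        "AU15": [(48, -0.05, 0.12), (54, 0.05, 0.12)],
        "AU17": [(8, 0.0, -0.18)],
        "AU20": [(48, -0.12, 0.03), (54, 0.12, 0.03)],
        "AU25": [(51, 0.0, 0.08), (57, 0.0, -0.02)],
        "AU26": [(8, 0.0, -0.10)],
        "AU07": [(40, 0.0, 0.05), (47, 0.0, 0.05)],
        "AU10": [(50, 0.0, -0.08), (52, 0.0, -0.08)],
        "AU14": [(48, -0.05, 0.05), (54, 0.05, 0.05)],
        "AU23": [(51, 0.0, 0.05)],
    }
    return MuscleHeatmapSpec(anchors=anchors)
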