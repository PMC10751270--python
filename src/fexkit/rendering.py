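"""Deterministic rasterization of a stylized, anonymous face from 68 landmarks.

Rendering is done with Pillow at a supersampled resolution and averaged down
(BOX filter), which gives anti-aliased 1-px strokes with bit-identical output
for identical inputs.  The face frame used throughout the package is the
normalized landmark frame (centroid near the origin, interocular distance 1);
:func:`normalized_to_canvas` maps it onto a pixel canvas with a fixed scale so
that AU deformations visibly move on screen.
"""

from __future__ import annotations

import numpy as np
from PIL import Image, ImageDraw

__all__ = ["normalized_to_canvas", "render_face"]

# the normalized face (brows to chin) spans roughly y in [-0.3, 1.6]; this
# fixed window centers it on the canvas with margin for deformations/jitter
FRAME_CENTER = (0.0, 0.65)
FRAME_SPAN = 3.4

_INK = 25          # stroke gray level (0-255)
_EYE_FILL = 45
_MOUTH_FILL = 95
_INNER_MOUTH_FILL = 35


def normalized_to_canvas(points: np.ndarray, canvas_size: int,
                         scale: float | None = None,
                         center: tuple[float, float] | None = None) -> np.ndarray:
    """Map normalized-frame coordinates to pixel coordinates on a square canvas."""
    pts = np.asarray(points, dtype=float)
    if scale is None:
        scale = canvas_size / FRAME_SPAN
    if center is None:
        center = (canvas_size / 2.0, canvas_size / 2.0)
    out = np.empty_like(pts)
    out[:, 0] = (pts[:, 0] - FRAME_CENTER[0]) * scale + center[0]
    out[:, 1] = (pts[:, 1] - FRAME_CENTER[1]) * scale + center[1]
    return out


def render_face(canvas_points: np.ndarray, canvas_size: int,
                background: float = 0.5, supersample: int = 2) -> np.ndarray:
    """Rasterize a face outline from landmarks already in canvas coordinates.

    Draws the jaw, brows and nose as open polylines and the eyes and mouth as
    filled polygons.  Returns a float array in [0, 1] of shape
    ``(canvas_size, canvas_size)``.
    """
    pts = np.asarray(canvas_points, dtype=float)
    if pts.shape != (68, 2):
        raise ValueError("render_face expects (68, 2) canvas coordinates")
    ss = int(supersample)
    big = canvas_size * ss
    img = Image.new("L", (big, big), int(round(background * 255)))
    draw = ImageDraw.Draw(img)
    p = [tuple(xy) for xy in (pts * ss)]

    def polyline(idx, closed=False, width=ss):
        seq = [p[i] for i in idx]
        if closed:
            seq.append(seq[0])
        draw.line(seq, fill=_INK, width=width)

    # jaw, brows, nose bridge, nostril line
    polyline(range(0, 17))
    polyline(range(17, 22))
    polyline(range(22, 27))
    polyline(range(27, 31))
    polyline(range(31, 36))
    # eyes: filled polygons
    draw.polygon([p[i] for i in range(36, 42)], fill=_EYE_FILL, outline=_INK)
    draw.polygon([p[i] for i in range(42, 48)], fill=_EYE_FILL, outline=_INK)
    # mouth: outer lip contour filled, inner opening darker
    draw.polygon([p[i] for i in range(48, 60)], fill=_MOUTH_FILL, outline=_INK)
    draw.polygon([p[i] for i in range(60, 68)], fill=_INNER_MOUTH_FILL, outline=_INK)

    if ss > 1:
        img = img.resize((canvas_size, canvas_size), Image.BOX)
    return np.asarray(img, dtype=float) / 255.0
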