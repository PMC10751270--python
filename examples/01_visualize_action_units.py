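"""Render stylized faces from action-unit activations.

Builds the packaged AU -> landmark face model, activates a few action units,
and saves renders (neutral, smile, surprise, smile + muscle heatmap) plus a
neutral-to-smile morph strip.  The printed numbers are landmark displacements
in interocular units: how far the mouth corners / brows move per unit of AU
activation.
"""

import pathlib

import numpy as np
from PIL import Image

import fexkit as fx

out = pathlib.Path("example_output")
out.mkdir(exist_ok=True)

model = fx.default_face_model()
spec = fx.default_heatmap_spec()

expressions = {
    "neutral": "neutral",
    "smile": {"AU06": 0.8, "AU12": 1.0},
    "surprise": {"AU01": 1.0, "AU02": 1.0, "AU05": 0.9, "AU26": 0.9},
}
for name, au in expressions.items():
    img = fx.plot_face(model, au, canvas_size=256)
    Image.fromarray((img * 255).astype("uint8")).save(out / f"face_{name}.png")

heat = fx.plot_face(model, {"AU06": 0.8, "AU12": 1.0}, heatmap=spec)
Image.fromarray((heat * 255).astype("uint8")).save(out / "face_smile_heatmap.png")

frames = fx.animate_face(model, "neutral", model.au_vector({"AU12": 1.0}), n_frames=6)
strip = np.concatenate(frames, axis=1)
Image.fromarray((strip * 255).astype("uint8")).save(out / "morph_neutral_to_smile.png")

neutral = fx.generate_landmarks(model, np.zeros(model.K)).points
smile = fx.generate_landmarks(model, model.au_vector({"AU12": 1.0})).points
corner_dx = smile[54, 0] - neutral[54, 0]
corner_dy = smile[54, 1] - neutral[54, 1]
print(f"AU12 at 1.0 moves the left mouth corner by ({corner_dx:+.3f}, {corner_dy:+.3f}) "
      "interocular units (outward and upward: a smile).")

brow = fx.generate_landmarks(model, model.au_vector({"AU01": 1.0})).points
print(f"AU01 at 1.0 raises the inner brow by {neutral[21, 1] - brow[21, 1]:.3f} "
      "interocular units.")
print(f"renders written to {out}/")
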