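"""Robustness of the AU detector to occlusion, rotation and luminance.

Trains a reduced bundle, then re-evaluates F1 after masking face regions
with black boxes (landmark-guided), rotating the image + landmarks in-plane,
and scaling brightness.  The expected pattern: masking the eyes hurts the
brow/eye AUs (1, 2, 4, 5, 6) most, masking the mouth hurts the mouth AUs
(12, 15, 20, 25, 26) most, and F1 decays as rotation grows (the detector is
trained on upright faces only).
"""

import numpy as np

import fexkit as fx

bundle, *_ = fx.train_synth_bundle(seed=7, n_au=800, n_emotion=200)
test = fx.make_dataset(fx.SynthRecipe(n_faces=150, seed=8))
gt = np.array([r.au_binary for r in test])


def mean_f1(transform=None):
    feats = []
    for r in test:
        img, lms = r.image, r.landmarks
        if transform is not None:
            img, lms = transform(img, lms)
        feats.append(fx.extract_features(img, lms, bundle.config))
    pred = (fx.detect_aus(bundle, np.vstack(feats)) >= 0.5).astype(int)
    return np.array([fx.f1_binary(pred[:, j], gt[:, j]) for j in range(12)])


base = mean_f1()
print(f"baseline mean F1: {base.mean():.3f}")

eye_idx = [fx.AU_NAMES.index(a) for a in ("AU01", "AU02", "AU04", "AU05", "AU06")]
mouth_idx = [fx.AU_NAMES.index(a) for a in ("AU12", "AU15", "AU20", "AU25", "AU26")]
for region in ("eyes", "nose", "mouth"):
    f1 = mean_f1(lambda im, lm, r=region: (fx.occlude(im, lm, r), lm))
    print(f"occluding {region:5s}: brow/eye AUs F1 {f1[eye_idx].mean():.3f}, "
          f"mouth AUs F1 {f1[mouth_idx].mean():.3f}")

print("in-plane rotation (desk-scale stand-in for out-of-plane head rotation):")
for deg in (0, 15, 30, 45):
    f1 = mean_f1(lambda im, lm, d=deg: fx.rotate(im, lm, d))
    print(f"  {deg:2d} deg: mean F1 {f1.mean():.3f}")

for level in ("low", "high"):
    f1 = mean_f1(lambda im, lm, lv=level: (fx.perturb_brightness(im, lv, seed=0)[0], lm))
    print(f"brightness {level}: mean F1 {f1.mean():.3f}")
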