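"""Synthetic-data engine: labeled stylized face images and
condition-structured facial time series.

Faces are generated by driving the packaged AU -> landmark model
(:func:`fexkit.facemodel.default_face_model`) with sampled action-unit
activation vectors, adding Gaussian landmark jitter, rasterizing the
deformed landmarks as a stylized anonymous face, and applying mild
brightness/placement jitter.  Every record carries full ground truth
(box, landmarks, AU occurrences and intensities, emotion label, nuisance
parameters), so detector training, benchmark metrics, robustness
perturbations and the Fex statistics are all testable without any external
dataset.

The canonical AU -> emotion map (restricted to the 12 detection AUs) is an
EMFACS-style convention adopted by this package: happiness {6, 12}; sadness
{1, 4, 15}; surprise {1, 2, 5, 26}; fear {1, 2, 4, 5, 20, 26}; anger
{4, 5, 17}; disgust {9, 15, 25}; neutral = nothing active.

The time-series generator emulates the two-condition experiment design:
AU probability channels sit at the 0.5 maximal-uncertainty baseline, the
"good news" condition raises AU06/AU12/AU25, and temporal noise is
first-order autoregressive (coefficient 0.7) so that video-grouped
cross-validation is meaningfully harder than frame-level folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .detectors import AU_NAMES, EMOTIONS, PreprocessConfig, fit_detector_bundle
from .exceptions import ConfigurationError
from .facemodel import AUFaceModel, default_face_model, generate_landmarks
from .fexdata import (AU_COLS, EMOTION_COLS, FEX_COLUMNS, FexTable)
from .geometry import BoundingBox, LandmarkSet68
from .rendering import normalized_to_canvas, render_face

__all__ = [
    "SynthRecipe",
    "SynthRecord",
    "CANONICAL_EMOTION_MAP",
    "sample_au_vectors",
    "make_dataset",
    "make_fex_timeseries",
    "train_synth_bundle",
]

# binary AU prototype per emotion, over the 12 detection AUs
CANONICAL_EMOTION_MAP = {
    "happiness": ("AU06", "AU12"),
    "sadness": ("AU01", "AU04", "AU15"),
    "surprise": ("AU01", "AU02", "AU05", "AU26"),
    "fear": ("AU01", "AU02", "AU04", "AU05", "AU20", "AU26"),
    "anger": ("AU04", "AU05", "AU17"),
    "disgust": ("AU09", "AU15", "AU25"),
    "neutral": (),
}


@dataclass(frozen=True)
class SynthRecipe:
    """Generation law for a labeled synthetic face dataset.

    ``sampling="independent"`` draws each AU as an independent Bernoulli
    occurrence with a uniform intensity; ``sampling="emotion"`` draws an
    emotion category uniformly and activates its prototype AUs.
    """

    n_faces: int = 400
    au_probability: float = 0.3
    intensity_range: tuple[float, float] = (0.5, 1.0)
    landmark_noise: float = 0.01          # interocular units
    canvas_size: int = 128
    brightness_jitter: tuple[float, float] = (0.9, 1.1)
    scale_jitter: tuple[float, float] = (0.9, 1.1)
    shift_jitter: float = 0.04            # fraction of canvas
    sampling: str = "independent"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.au_probability <= 1.0:
            raise ConfigurationError("au_probability must lie in [0, 1]")
        if self.landmark_noise < 0:
            raise ConfigurationError("landmark_noise must be >= 0")
        if self.sampling not in ("independent", "emotion"):
            raise ConfigurationError("sampling must be 'independent' or 'emotion'")
        if self.canvas_size < 48:
            raise ConfigurationError("canvas too small for the face scale")


@dataclass
class SynthRecord:
    """One generated face with full ground truth."""

    image: np.ndarray
    box: BoundingBox
    landmarks: LandmarkSet68
    au_binary: np.ndarray         # (12,) ints
    au_intensity: np.ndarray      # (12,) floats in [0, 1]
    emotion: str
    nuisance: dict = field(default_factory=dict)


def _emotion_from_pattern(binary: np.ndarray) -> str:
    """Label a binary AU pattern via exact prototype match, else neutral."""
    pattern = tuple(np.asarray(AU_NAMES)[np.asarray(binary, dtype=bool)])
    for emo, proto in CANONICAL_EMOTION_MAP.items():
        if pattern == proto:
            return emo
    return "neutral"


def sample_au_vectors(recipe: SynthRecipe, n: int,
                      rng: np.random.Generator | None = None):
    """Draw (n, 12) AU intensities + binary occurrence labels (+ emotions).

    Returns ``(intensities, binary, emotions)``; binary label is exactly
    ``intensity > 0``.
    """
    if rng is None:
        rng = np.random.default_rng(recipe.seed)
    lo, hi = recipe.intensity_range
    K = len(AU_NAMES)
    intens = np.zeros((n, K))
    emotions = []
    if recipe.sampling == "independent":
        occ = rng.random((n, K)) < recipe.au_probability
        intens[occ] = rng.uniform(lo, hi, size=int(occ.sum()))
        for row in occ:
            emotions.append(_emotion_from_pattern(row))
    else:
        emo_names = list(CANONICAL_EMOTION_MAP)
        for i in range(n):
            emo = emo_names[int(rng.integers(len(emo_names)))]
            emotions.append(emo)
            for au in CANONICAL_EMOTION_MAP[emo]:
                intens[i, AU_NAMES.index(au)] = rng.uniform(lo, hi)
    binary = (intens > 0).astype(int)
    return intens, binary, emotions


def make_dataset(recipe: SynthRecipe, model: AUFaceModel | None = None) -> list:
    """Generate a list of :class:`SynthRecord` according to the recipe.

    Deterministic: the same recipe produces byte-identical images.
    """
    if model is None:
        model = default_face_model()
    rng = np.random.default_rng(recipe.seed)
    intens, binary, emotions = sample_au_vectors(recipe, recipe.n_faces, rng)
    size = recipe.canvas_size
    base_scale = size / 3.4
    records = []
    for i in range(recipe.n_faces):
        a = np.zeros(model.K)
        a[: len(AU_NAMES)] = intens[i]
        lms_norm = generate_landmarks(model, a).points
        if recipe.landmark_noise > 0:
            lms_norm = lms_norm + rng.normal(0.0, recipe.landmark_noise, (68, 2))
        scale = base_scale * rng.uniform(*recipe.scale_jitter)
        shift = rng.uniform(-recipe.shift_jitter, recipe.shift_jitter, 2) * size
        center = (size / 2.0 + shift[0], size / 2.0 + shift[1])
        canvas_pts = normalized_to_canvas(lms_norm, size, scale=scale, center=center)
        if canvas_pts.min() < -size * 0.25 or canvas_pts.max() > size * 1.25:
            raise ConfigurationError("canvas too small for the face scale")
        img = render_face(canvas_pts, size)
        bfac = float(rng.uniform(*recipe.brightness_jitter))
        img = np.clip(img * bfac, 0.0, 1.0)
        lms = LandmarkSet68(canvas_pts)
        records.append(SynthRecord(
            image=img,
            box=lms.bounding_box(pad=2.0),
            landmarks=lms,
            au_binary=binary[i].copy(),
            au_intensity=intens[i].copy(),
            emotion=emotions[i],
            nuisance={"brightness": bfac, "rotation": 0.0,
                      "seed": recipe.seed, "index": i},
        ))
    return records


_DEFAULT_EFFECT = {
    "good_news": {"AU06": 0.15, "AU12": 0.15, "AU25": 0.15},
    "bad_news": {},
}


def make_fex_timeseries(
    n_videos_per_condition: int = 10,
    n_frames: int = 300,
    effect_spec: dict | None = None,
    noise_sd: float = 0.05,
    ar_coef: float = 0.7,
    seed: int = 0,
) -> FexTable:
    """Two-condition AU probability time series as a :class:`FexTable`.

    Each video's AU channels are ``0.5 + condition effect + AR(1) noise``
    clipped to [0, 1]; emotion channels are a softmax over prototype-match
    scores of the AU channels.  Landmark/box/pose columns carry a static
    template face plus small per-frame jitter.
    """
    if effect_spec is None:
        effect_spec = _DEFAULT_EFFECT
    conditions = list(effect_spec)
    if len(conditions) != 2:
        raise ConfigurationError("effect_spec must name exactly two conditions")
    rng = np.random.default_rng(seed)
    model = default_face_model()
    base_pts = normalized_to_canvas(model.template.points, 128)
    stat_sd = noise_sd / np.sqrt(max(1e-12, 1.0 - ar_coef ** 2))
    rows = []
    for cond in conditions:
        effects = effect_spec[cond]
        for au, shift in effects.items():
            if not 0.0 <= 0.5 + shift <= 1.0:
                import warnings

                warnings.warn(f"effect for {au} pushes the mean outside [0, 1]; clipping")
        for v in range(n_videos_per_condition):
            vid = f"{cond}_{v:03d}"
            au_mat = np.empty((n_frames, len(AU_NAMES)))
            for j, au in enumerate(AU_NAMES):
                mean = 0.5 + effects.get(au, 0.0)
                x = rng.normal(0.0, stat_sd)
                for t in range(n_frames):
                    x = ar_coef * x + rng.normal(0.0, noise_sd)
                    au_mat[t, j] = mean + x
            au_mat = np.clip(au_mat, 0.0, 1.0)
            # emotion channels: softmax over prototype-match scores
            emo_scores = np.empty((n_frames, len(EMOTIONS)))
            for e, emo in enumerate(EMOTIONS):
                proto = CANONICAL_EMOTION_MAP[emo]
                if proto:
                    idx = [AU_NAMES.index(a) for a in proto]
                    emo_scores[:, e] = au_mat[:, idx].mean(axis=1)
                else:
                    emo_scores[:, e] = 0.5
            emo_scores += rng.normal(0.0, 0.02, emo_scores.shape)
            expo = np.exp(emo_scores / 0.1)
            emo_mat = expo / expo.sum(axis=1, keepdims=True)
            pts = base_pts[None, :, :] + rng.normal(0.0, 0.5, (n_frames, 68, 2))
            for t in range(n_frames):
                lo = pts[t].min(axis=0)
                hi = pts[t].max(axis=0)
                row = {
                    "frame": t,
                    "input": vid,
                    "FaceRectX": lo[0] - 2, "FaceRectY": lo[1] - 2,
                    "FaceRectWidth": hi[0] - lo[0] + 4,
                    "FaceRectHeight": hi[1] - lo[1] + 4,
                    "FaceScore": 1.0,
                    "Pitch": rng.normal(0.0, 3.0),
                    "Roll": rng.normal(0.0, 3.0),
                    "Yaw": rng.normal(0.0, 3.0),
                    "session": cond,
                }
                for i in range(68):
                    row[f"x_{i}"] = pts[t, i, 0]
                    row[f"y_{i}"] = pts[t, i, 1]
                row.update(dict(zip(AU_COLS, au_mat[t])))
                row.update(dict(zip(EMOTION_COLS, emo_mat[t])))
                rows.append(row)
    df = pd.DataFrame(rows)[FEX_COLUMNS]
    return FexTable(df)


def train_synth_bundle(seed: int = 7, n_au: int = 2000, n_emotion: int = 1400,
                       algorithm: str = "svm",
                       config: PreprocessConfig = PreprocessConfig(),
                       recipe: SynthRecipe | None = None):
    """Convenience: generate AU + emotion training sets with the default
    recipe and fit a :class:`~fexkit.detectors.DetectorBundle`.

    Returns ``(bundle, au_records, emotion_records)``.
    """
    base = recipe if recipe is not None else SynthRecipe()
    au_recipe = replace(base, n_faces=n_au, sampling="independent", seed=seed)
    emo_recipe = replace(base, n_faces=n_emotion, sampling="emotion", seed=seed + 1)
    au_records = make_dataset(au_recipe)
    emo_records = make_dataset(emo_recipe)
    bundle = fit_detector_bundle(
        images=[r.image for r in au_records],
        landmark_sets=[r.landmarks for r in au_records],
        au_labels=np.array([r.au_binary for r in au_records]),
        emotion_images=[r.image for r in emo_records],
        emotion_landmarks=[r.landmarks for r in emo_records],
        emotion_labels=[r.emotion for r in emo_records],
        algorithm=algorithm, config=config, seed=seed,
    )
    return bundle, au_records, emo_records
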