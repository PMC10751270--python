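"""Per-AU binary classifiers and the 7-class emotion classifier.

Both detectors operate on PCA-compressed HOG features (see
:mod:`fexkit.features`).  Each of the 12 action units gets its own
independent binary model — either a linear max-margin classifier whose
margin is mapped to [0, 1] by a Platt-style logistic link fitted on the
training margins, or gradient-boosted trees which emit calibrated
probabilities natively.  The emotion detector is a 7-class linear
max-margin model with per-class logistic links, normalized so the seven
probabilities sum to one.  Class imbalance is handled with
inverse-frequency sample weights.

A fitted :class:`DetectorBundle` (PCA basis + per-AU classifiers + emotion
classifier + preprocessing config) serializes to a single versioned archive
whose bytes are identical across retrains with the same data and seed.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC
from xgboost import XGBClassifier

from .exceptions import CompatibilityError
from .features import (FacePatch, PCABasis, PreprocessConfig, align_crop,
                       fit_pca, hog_features, project)
from .geometry import LandmarkSet68

__all__ = [
    "AU_NAMES",
    "EMOTIONS",
    "AUVector",
    "EmotionVector",
    "DetectorBundle",
    "train_au_detector",
    "train_emotion_detector",
    "detect_aus",
    "detect_emotions",
    "extract_features",
    "fit_detector_bundle",
    "save_bundle",
    "load_bundle",
]

AU_NAMES = (
    "AU01", "AU02", "AU04", "AU05", "AU06", "AU09",
    "AU12", "AU15", "AU17", "AU20", "AU25", "AU26",
)
EMOTIONS = ("anger", "disgust", "fear", "happiness", "sadness", "surprise", "neutral")

_BUNDLE_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class AUVector:
    """Occurrence probabilities for the 12 detection AUs."""

    values: dict

    def __post_init__(self):
        if tuple(self.values.keys()) != AU_NAMES:
            raise ValueError(f"AUVector requires exactly the keys {AU_NAMES} in order")
        for k, v in self.values.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{k} probability {v} outside [0, 1]")

    def __getitem__(self, key):
        return self.values[key]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in AU_NAMES])

    def binary(self, threshold: float = 0.5) -> np.ndarray:
        """Binary calls used for F1 scoring."""
        return (self.as_array() >= threshold).astype(int)

    @classmethod
    def from_array(cls, arr) -> "AUVector":
        a = np.asarray(arr, dtype=float).ravel()
        if a.shape[0] != len(AU_NAMES):
            raise ValueError("expected 12 values")
        return cls(dict(zip(AU_NAMES, a)))


@dataclass(frozen=True)
class EmotionVector:
    """Probabilities over the seven emotion categories; sums to 1."""

    values: dict

    def __post_init__(self):
        if tuple(self.values.keys()) != EMOTIONS:
            raise ValueError(f"EmotionVector requires exactly the keys {EMOTIONS} in order")
        arr = np.array(list(self.values.values()), dtype=float)
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("emotion probabilities must lie in [0, 1]")
        if abs(arr.sum() - 1.0) > 1e-6:
            raise ValueError(f"emotion probabilities must sum to 1, got {arr.sum()}")

    def __getitem__(self, key):
        return self.values[key]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in EMOTIONS])

    def argmax(self) -> str:
        return EMOTIONS[int(np.argmax(self.as_array()))]

    @classmethod
    def from_array(cls, arr) -> "EmotionVector":
        a = np.asarray(arr, dtype=float).ravel()
        if a.shape[0] != len(EMOTIONS):
            raise ValueError("expected 7 values")
        return cls(dict(zip(EMOTIONS, a)))


def _inverse_frequency_weights(y: np.ndarray) -> np.ndarray:
    classes, counts = np.unique(y, return_counts=True)
    freq = dict(zip(classes.tolist(), counts.tolist()))
    n = len(y)
    return np.array([n / (len(classes) * freq[v]) for v in np.asarray(y).tolist()])


def _fit_platt(margins: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Logistic link p = sigmoid(a*m + b) fitted on training margins."""
    lr = LogisticRegression(C=1e3, solver="lbfgs", max_iter=1000)
    lr.fit(margins.reshape(-1, 1), y)
    return float(lr.coef_[0, 0]), float(lr.intercept_[0])


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


class LinearAUClassifier:
    """Linear max-margin binary classifier with a Platt logistic link."""

    algorithm = "max-margin-linear"

    def __init__(self, coef: np.ndarray, intercept: float, platt_a: float, platt_b: float):
        self.coef = np.asarray(coef, dtype=float).ravel()
        self.intercept = float(intercept)
        self.platt_a = float(platt_a)
        self.platt_b = float(platt_b)

    @classmethod
    def fit(cls, X, y, seed: int = 0) -> "LinearAUClassifier":
        w = _inverse_frequency_weights(y)
        svm = LinearSVC(C=1.0, dual=False, random_state=seed)
        svm.fit(X, y, sample_weight=w)
        margins = svm.decision_function(X)
        a, b = _fit_platt(margins, y)
        return cls(svm.coef_.ravel(), svm.intercept_[0], a, b)

    def decision(self, X) -> np.ndarray:
        return np.atleast_2d(X) @ self.coef + self.intercept

    def predict_proba(self, X) -> np.ndarray:
        return _sigmoid(self.platt_a * self.decision(X) + self.platt_b)

    def to_state(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
        }

    @classmethod
    def from_state(cls, state: dict) -> "LinearAUClassifier":
        return cls(np.array(state["coef"]), state["intercept"],
                   state["platt_a"], state["platt_b"])


class XGBAUClassifier:
    """Gradient-boosted-tree binary classifier (probability output native)."""

    algorithm = "gradient-boosted-trees"

    def __init__(self, booster):
        self.booster = booster

    @classmethod
    def fit(cls, X, y, seed: int = 0) -> "XGBAUClassifier":
        w = _inverse_frequency_weights(y)
        m = XGBClassifier(
            n_estimators=150, max_depth=3, learning_rate=0.2,
            subsample=1.0, colsample_bytree=1.0, tree_method="hist",
            n_jobs=1, random_state=seed, eval_metric="logloss",
        )
        m.fit(np.asarray(X), np.asarray(y), sample_weight=w)
        return cls(m.get_booster())

    def predict_proba(self, X) -> np.ndarray:
        # binary:logistic objective -> inplace_predict returns probabilities
        return np.asarray(
            self.booster.inplace_predict(np.ascontiguousarray(np.atleast_2d(X))),
            dtype=float,
        )

    def to_state(self) -> dict:
        raw = self.booster.save_raw(raw_format="json")
        return {"algorithm": self.algorithm, "booster_json": bytes(raw).decode()}

    @classmethod
    def from_state(cls, state: dict) -> "XGBAUClassifier":
        import xgboost

        booster = xgboost.Booster()
        booster.load_model(bytearray(state["booster_json"].encode()))
        return cls(booster)


class EmotionClassifier:
    """One-vs-rest linear max-margin classifier with per-class logistic links;
    class probabilities are normalized to sum to one."""

    def __init__(self, coef: np.ndarray, intercept: np.ndarray,
                 platt: np.ndarray, classes: tuple[str, ...]):
        self.coef = np.asarray(coef, dtype=float)          # (C, k)
        self.intercept = np.asarray(intercept, dtype=float)  # (C,)
        self.platt = np.asarray(platt, dtype=float)        # (C, 2)
        self.classes = tuple(classes)

    @classmethod
    def fit(cls, X, labels, seed: int = 0) -> "EmotionClassifier":
        y = np.asarray(labels)
        classes = tuple(sorted(np.unique(y).tolist()))
        if len(classes) < 2:
            raise ValueError("emotion training requires at least 2 classes")
        w = _inverse_frequency_weights(y)
        svm = LinearSVC(C=1.0, dual=False, random_state=seed)
        svm.fit(X, y, sample_weight=w)
        margins = svm.decision_function(X)
        if margins.ndim == 1:  # binary case: one margin column per class
            margins = np.column_stack([-margins, margins])
            coef = np.vstack([-svm.coef_, svm.coef_])
            intercept = np.array([-svm.intercept_[0], svm.intercept_[0]])
        else:
            coef = svm.coef_
            intercept = svm.intercept_
        platt = np.empty((len(classes), 2))
        for j, c in enumerate(classes):
            platt[j] = _fit_platt(margins[:, j], (y == c).astype(int))
        return cls(coef, intercept, platt, classes)

    def predict_proba(self, X) -> np.ndarray:
        X = np.atleast_2d(X)
        margins = X @ self.coef.T + self.intercept
        probs = _sigmoid(self.platt[:, 0] * margins + self.platt[:, 1])
        total = probs.sum(axis=1, keepdims=True)
        # degenerate all-zero rows fall back to uniform
        uniform = np.full_like(probs, 1.0 / probs.shape[1])
        return np.where(total > 0, probs / np.maximum(total, 1e-300), uniform)

    def predict(self, X) -> np.ndarray:
        return np.array([self.classes[i] for i in np.argmax(self.predict_proba(X), axis=1)])

    def to_state(self) -> dict:
        return {
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "platt": self.platt.tolist(),
            "classes": list(self.classes),
        }

    @classmethod
    def from_state(cls, state: dict) -> "EmotionClassifier":
        return cls(np.array(state["coef"]), np.array(state["intercept"]),
                   np.array(state["platt"]), tuple(state["classes"]))


_AU_ALGORITHMS = {
    "svm": LinearAUClassifier,
    "max-margin-linear": LinearAUClassifier,
    "xgb": XGBAUClassifier,
    "gradient-boosted-trees": XGBAUClassifier,
}


def train_au_detector(scores: np.ndarray, labels: np.ndarray,
                      algorithm: str = "xgb", seed: int = 0) -> dict:
    """Train 12 independent binary AU classifiers on PCA scores.

    ``labels`` is an (n, 12) binary matrix ordered as :data:`AU_NAMES`.
    Raises a per-AU error when an AU column contains a single class.
    """
    if algorithm not in _AU_ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; valid: {sorted(_AU_ALGORITHMS)}")
    X = np.asarray(scores, dtype=float)
    Y = np.asarray(labels)
    if Y.shape != (X.shape[0], len(AU_NAMES)):
        raise ValueError(f"labels must be (n, 12), got {Y.shape}")
    cls = _AU_ALGORITHMS[algorithm]
    out = {}
    for j, name in enumerate(AU_NAMES):
        col = Y[:, j].astype(int)
        if len(np.unique(col)) < 2:
            raise ValueError(f"cannot train {name}: labels contain a single class")
        out[name] = cls.fit(X, col, seed=seed)
    return out


def train_emotion_detector(scores: np.ndarray, labels, seed: int = 0) -> EmotionClassifier:
    """Train the 7-class linear emotion classifier on PCA scores."""
    return EmotionClassifier.fit(np.asarray(scores, dtype=float), labels, seed=seed)


@dataclass
class DetectorBundle:
    """Everything needed to run detection: PCA basis, per-AU classifiers,
    emotion classifier, and the preprocessing config they were trained under."""

    pca: PCABasis
    au_classifiers: dict
    emotion_classifier: EmotionClassifier | None
    config: PreprocessConfig
    au_algorithm: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if tuple(self.au_classifiers.keys()) != AU_NAMES:
            raise ValueError("au_classifiers must cover exactly the 12 detection AUs in order")


def extract_features(image: np.ndarray, lms: LandmarkSet68,
                     config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Run the full patch -> hull-masked HOG front-end for one face."""
    patch = align_crop(image, lms, patch_size=config.patch_size)
    return hog_features(patch, orientations=config.hog_orientations,
                        cell=config.hog_cell, block=config.hog_block)


def _project_checked(bundle: DetectorBundle, features: np.ndarray) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != bundle.pca.d:
        raise CompatibilityError(
            f"feature length {x.shape[1]} does not match the bundle's preprocessing "
            f"config (expected HOG length {bundle.pca.d})"
        )
    return project(bundle.pca, x), single


def detect_aus(bundle: DetectorBundle, features: np.ndarray):
    """AU probabilities for one HOG vector (-> :class:`AUVector`) or a matrix
    of vectors (-> (n, 12) array)."""
    scores, single = _project_checked(bundle, features)
    probs = np.column_stack([
        np.clip(bundle.au_classifiers[name].predict_proba(scores), 0.0, 1.0)
        for name in AU_NAMES
    ])
    if single:
        return AUVector.from_array(probs[0])
    return probs


def detect_emotions(bundle: DetectorBundle, features: np.ndarray):
    """Emotion probabilities for one HOG vector (-> :class:`EmotionVector`)
    or a matrix of vectors (-> (n, 7) array ordered as :data:`EMOTIONS`)."""
    if bundle.emotion_classifier is None:
        raise ValueError("bundle has no fitted emotion classifier")
    scores, single = _project_checked(bundle, features)
    raw = bundle.emotion_classifier.predict_proba(scores)
    # reorder classifier classes to the canonical emotion order
    order = [bundle.emotion_classifier.classes.index(e) for e in EMOTIONS]
    probs = raw[:, order]
    probs = probs / probs.sum(axis=1, keepdims=True)
    if single:
        return EmotionVector.from_array(probs[0])
    return probs


def fit_detector_bundle(
    images, landmark_sets, au_labels,
    emotion_images=None, emotion_landmarks=None, emotion_labels=None,
    algorithm: str = "xgb",
    config: PreprocessConfig = PreprocessConfig(),
    seed: int = 0,
) -> DetectorBundle:
    """End-to-end training: HOG extraction, PCA fit, AU + emotion classifiers.

    The PCA basis is fitted on the pooled HOG features of the AU training set
    and (when given) the emotion training set, so both heads share one
    compression.
    """
    hog_au = np.vstack([extract_features(im, lm, config)
                        for im, lm in zip(images, landmark_sets)])
    blocks = [hog_au]
    if emotion_images is not None:
        hog_emo = np.vstack([extract_features(im, lm, config)
                             for im, lm in zip(emotion_images, emotion_landmarks)])
        blocks.append(hog_emo)
    basis = fit_pca(np.vstack(blocks), config.pca_retained_variance)
    scores_au = project(basis, hog_au)
    au_clfs = train_au_detector(scores_au, au_labels, algorithm=algorithm, seed=seed)
    emo_clf = None
    if emotion_images is not None:
        emo_clf = train_emotion_detector(project(basis, hog_emo), emotion_labels, seed=seed)
    return DetectorBundle(
        pca=basis, au_classifiers=au_clfs, emotion_classifier=emo_clf,
        config=config, au_algorithm=algorithm,
        metadata={"seed": seed, "n": int(len(images)), "created": None},
    )


# ----------------------------------------------------------------------------
# serialization: one versioned zip archive, byte-deterministic
# ----------------------------------------------------------------------------

def _npy_bytes(arr: np.ndarray) -> bytes:
    buf = io.BytesIO()
    np.save(buf, np.ascontiguousarray(arr))
    return buf.getvalue()


def _npy_from_bytes(raw: bytes) -> np.ndarray:
    return np.load(io.BytesIO(raw), allow_pickle=False)


def save_bundle(bundle: DetectorBundle, path) -> None:
    """Write the bundle to a single zip archive with a versioned schema.

    Timestamps inside the archive are fixed, so identical bundles produce
    identical bytes.
    """
    meta = {
        "schema_version": _BUNDLE_SCHEMA_VERSION,
        "config": bundle.config.to_dict(),
        "au_algorithm": bundle.au_algorithm,
        "metadata": bundle.metadata,
        "pca_retained_variance": bundle.pca.retained_variance,
        "au_states": {name: clf.to_state() for name, clf in bundle.au_classifiers.items()},
        "emotion_state": (bundle.emotion_classifier.to_state()
                          if bundle.emotion_classifier is not None else None),
    }
    entries = [
        ("meta.json", json.dumps(meta, sort_keys=True).encode()),
        ("pca_mean.npy", _npy_bytes(bundle.pca.mean)),
        ("pca_components.npy", _npy_bytes(bundle.pca.components)),
        ("pca_evr.npy", _npy_bytes(bundle.pca.explained_variance_ratio)),
    ]
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name, payload in entries:
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, payload)


def load_bundle(path) -> DetectorBundle:
    with zipfile.ZipFile(path, "r") as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta["schema_version"] != _BUNDLE_SCHEMA_VERSION:
            raise CompatibilityError(
                f"bundle schema {meta['schema_version']} not supported"
            )
        basis = PCABasis(
            mean=_npy_from_bytes(zf.read("pca_mean.npy")),
            components=_npy_from_bytes(zf.read("pca_components.npy")),
            explained_variance_ratio=_npy_from_bytes(zf.read("pca_evr.npy")),
            retained_variance=meta["pca_retained_variance"],
        )
    au_clfs = {}
    for name in AU_NAMES:
        state = meta["au_states"][name]
        cls = _AU_ALGORITHMS[state["algorithm"]]
        au_clfs[name] = cls.from_state(state)
    emo = (EmotionClassifier.from_state(meta["emotion_state"])
           if meta["emotion_state"] is not None else None)
    return DetectorBundle(
        pca=basis, au_classifiers=au_clfs, emotion_classifier=emo,
        config=PreprocessConfig.from_dict(meta["config"]),
        au_algorithm=meta["au_algorithm"], metadata=meta["metadata"],
    )
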