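"""AU / emotion classifier training, prediction contracts, serialization."""

import numpy as np
import pytest

import fexkit as fx
from fexkit.detectors import (AU_NAMES, EMOTIONS, EmotionClassifier,
                              LinearAUClassifier, XGBAUClassifier,
                              train_au_detector, train_emotion_detector)
from fexkit.exceptions import CompatibilityError
from fexkit.features import PreprocessConfig, fit_pca
from fexkit.metrics import f1_binary


def separable_scores(rng, n=120, k=6):
    """Scores where each AU label is the sign of one coordinate, with a
    clear margin around zero."""
    X = rng.uniform(0.5, 2.0, size=(n, k)) * rng.choice([-1.0, 1.0], size=(n, k))
    Y = np.column_stack([(X[:, j % k] > 0).astype(int) for j in range(12)])
    return X, Y


# ------------------------------------------------------------- training

@pytest.mark.parametrize("algorithm", ["svm", "xgb"])
def test_separable_training_f1_is_one(algorithm):
    rng = np.random.default_rng(0)
    X, Y = separable_scores(rng)
    clfs = train_au_detector(X, Y, algorithm=algorithm, seed=0)
    for j, name in enumerate(AU_NAMES):
        pred = (clfs[name].predict_proba(X) >= 0.5).astype(int)
        assert f1_binary(pred, Y[:, j]) == 1.0


def test_single_class_au_error_names_the_au():
    rng = np.random.default_rng(1)
    X, Y = separable_scores(rng)
    Y[:, 3] = 1
    with pytest.raises(ValueError, match="AU05"):
        train_au_detector(X, Y, algorithm="svm")


def test_unknown_algorithm_rejected():
    rng = np.random.default_rng(2)
    X, Y = separable_scores(rng)
    with pytest.raises(ValueError, match="unknown algorithm"):
        train_au_detector(X, Y, algorithm="deep-net")


def test_label_permutation_null_collapses_to_baseline():
    """With labels independent of features, held-out F1 stays at the
    positive-rate baseline (no leakage through the pipeline)."""
    rng = np.random.default_rng(3)
    n, k, p = 300, 5, 0.3
    diffs = []
    for seed in range(20):
        r = np.random.default_rng(seed)
        X = r.normal(size=(n, k))
        y = (r.random(n) < p).astype(int)
        while len(np.unique(y[:200])) < 2 or y[200:].sum() == 0:
            y = (r.random(n) < p).astype(int)
        clf = LinearAUClassifier.fit(X[:200], y[:200], seed=seed)
        pred = (clf.predict_proba(X[200:]) >= 0.5).astype(int)
        held_f1 = f1_binary(pred, y[200:]) if y[200:].sum() else 0.0
        baseline = f1_binary(np.ones_like(y[200:]), y[200:])
        diffs.append(held_f1 - baseline)
    # on average a label-independent model cannot beat the trivial baseline
    assert np.mean(diffs) < 0.05


def test_linear_probability_monotone_in_margin():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(100, 4))
    y = (X[:, 0] + 0.3 * rng.normal(size=100) > 0).astype(int)
    clf = LinearAUClassifier.fit(X, y, seed=0)
    margins = np.linspace(-5, 5, 50)
    probs = 1 / (1 + np.exp(-(clf.platt_a * margins + clf.platt_b)))
    assert np.all(np.diff(probs) >= 0)
    assert np.all((probs >= 0) & (probs <= 1))


def test_training_is_deterministic_in_serialized_bytes(tmp_path):
    rng = np.random.default_rng(5)
    X, Y = separable_scores(rng, n=150)
    basis = fit_pca(rng.normal(size=(50, 30)), 0.95)
    rng2 = np.random.default_rng(6)
    emo_labels = np.array(EMOTIONS)[rng2.integers(0, 7, len(X))]
    Xp = np.pad(X, ((0, 0), (0, max(0, basis.k - X.shape[1]))))[:, :basis.k]

    def bundle_bytes(path):
        clfs = train_au_detector(Xp, Y, algorithm="xgb", seed=11)
        emo = train_emotion_detector(Xp, emo_labels, seed=11)
        b = fx.DetectorBundle(pca=basis, au_classifiers=clfs, emotion_classifier=emo,
                              config=PreprocessConfig(), au_algorithm="xgb",
                              metadata={"seed": 11, "n": len(X), "created": None})
        fx.save_bundle(b, path)
        return path.read_bytes()

    b1 = bundle_bytes(tmp_path / "a.zip")
    b2 = bundle_bytes(tmp_path / "b.zip")
    assert b1 == b2


# ------------------------------------------------------------ detection

def test_detect_aus_training_exemplar_and_totality(bundle, trained):
    _, au_records, _ = trained
    r = au_records[0]
    feats = fx.extract_features(r.image, r.landmarks, bundle.config)
    vec = fx.detect_aus(bundle, feats)
    assert isinstance(vec, fx.AUVector)
    arr = vec.as_array()
    assert np.all((arr >= 0) & (arr <= 1))
    # all-zero features are still a legal input: finite probabilities
    zero = fx.detect_aus(bundle, np.zeros(bundle.pca.d))
    assert np.all(np.isfinite(zero.as_array()))


def test_detect_aus_config_mismatch(bundle):
    with pytest.raises(CompatibilityError):
        fx.detect_aus(bundle, np.zeros(bundle.pca.d + 7))


def test_emotion_probabilities_sum_to_one(bundle):
    rng = np.random.default_rng(7)
    feats = rng.random((50, bundle.pca.d))
    probs = fx.detect_emotions(bundle, feats)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    single = fx.detect_emotions(bundle, feats[0])
    assert isinstance(single, fx.EmotionVector)
    assert abs(sum(single.values.values()) - 1.0) < 1e-6


def test_emotion_separable_training_accuracy():
    rng = np.random.default_rng(8)
    centers = rng.normal(scale=8.0, size=(7, 5))
    X = np.vstack([centers[i] + rng.normal(scale=0.3, size=(20, 5)) for i in range(7)])
    y = np.repeat(list(EMOTIONS), 20)
    clf = train_emotion_detector(X, y, seed=0)
    assert np.mean(clf.predict(X) == y) == 1.0


def test_emotion_single_class_error():
    rng = np.random.default_rng(9)
    with pytest.raises(ValueError, match="2 classes"):
        train_emotion_detector(rng.normal(size=(20, 3)), ["happiness"] * 20)


def test_au_vector_contracts():
    with pytest.raises(ValueError):
        fx.AUVector(dict(zip(AU_NAMES[:11], np.zeros(11))))
    with pytest.raises(ValueError):
        fx.AUVector.from_array(np.full(12, 1.5))
    v = fx.AUVector.from_array(np.linspace(0, 1, 12))
    assert np.array_equal(v.binary(0.5), (np.linspace(0, 1, 12) >= 0.5).astype(int))


def test_emotion_vector_contracts():
    with pytest.raises(ValueError):
        fx.EmotionVector.from_array(np.full(7, 0.2))  # sums to 1.4
    v = fx.EmotionVector.from_array(np.full(7, 1 / 7))
    assert v.argmax() in EMOTIONS


# --------------------------------------------------------- serialization

def test_bundle_round_trip(tmp_path, bundle, au_test_features):
    path = tmp_path / "bundle.zip"
    fx.save_bundle(bundle, path)
    loaded = fx.load_bundle(path)
    p1 = fx.detect_aus(bundle, au_test_features[:20])
    p2 = fx.detect_aus(loaded, au_test_features[:20])
    assert np.allclose(p1, p2, atol=1e-12)
    e1 = fx.detect_emotions(bundle, au_test_features[:20])
    e2 = fx.detect_emotions(loaded, au_test_features[:20])
    assert np.allclose(e1, e2, atol=1e-12)
    # re-saving the loaded bundle reproduces identical bytes
    path2 = tmp_path / "bundle2.zip"
    fx.save_bundle(loaded, path2)
    assert path.read_bytes() == path2.read_bytes()
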