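"""Shared fixtures: the default face model, one trained detector bundle
(linear variant, synthetic training set), and a held-out synthetic test set.

The bundle is trained once per session; the heavier end-to-end and
robustness tests all reuse it.
"""

import numpy as np
import pytest

import fexkit as fx


@pytest.fixture(scope="session")
def face_model():
    return fx.default_face_model()


@pytest.fixture(scope="session")
def trained():
    """(bundle, au_train_records, emotion_train_records), seed 7."""
    return fx.train_synth_bundle(seed=7, n_au=2000, n_emotion=1400)


@pytest.fixture(scope="session")
def bundle(trained):
    return trained[0]


@pytest.fixture(scope="session")
def au_test_set():
    """Held-out AU test set: independent sampling, seed 8, n=400."""
    records = fx.make_dataset(fx.SynthRecipe(n_faces=400, seed=8))
    return records


@pytest.fixture(scope="session")
def au_test_features(au_test_set):
    return np.vstack([fx.extract_features(r.image, r.landmarks) for r in au_test_set])


@pytest.fixture(scope="session")
def au_test_labels(au_test_set):
    return np.array([r.au_binary for r in au_test_set])


@pytest.fixture(scope="session")
def emotion_test_set():
    """Held-out emotion test set: emotion-prototype sampling, seed 8, n=400."""
    from dataclasses import replace

    recipe = replace(fx.SynthRecipe(n_faces=400, seed=8), sampling="emotion")
    return fx.make_dataset(recipe)


def per_au_f1(bundle, features, labels):
    pred = (fx.detect_aus(bundle, features) >= 0.5).astype(int)
    return np.array([fx.f1_binary(pred[:, j], labels[:, j]) for j in range(len(fx.AU_NAMES))])
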