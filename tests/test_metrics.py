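"""Benchmark metrics: IoU, average precision, NME, pose MAE, F1."""

import numpy as np
import pytest

import fexkit as fx
from fexkit.exceptions import UndefinedMetricError
from fexkit.metrics import DetectionSet


def box(x, y, w, h, score=1.0):
    return fx.BoundingBox(x, y, w, h, score)


# -------------------------------------------------------------------- IoU

def test_iou_examples():
    a = box(0, 0, 2, 2)
    assert fx.iou(a, a) == 1.0
    assert fx.iou(a, box(10, 10, 2, 2)) == 0.0
    assert fx.iou(a, box(1, 0, 2, 2)) == pytest.approx(2 / 6)


# ------------------------------------------------------- average precision

def test_ap_perfect_detection():
    gts = [box(0, 0, 5, 5), box(20, 20, 4, 4)]
    preds = [box(0, 0, 5, 5, 0.9), box(20, 20, 4, 4, 0.8)]
    ds = DetectionSet(preds, ["im", "im"], gts, ["im", "im"])
    assert fx.average_precision(ds) == 1.0


def test_ap_miss_then_hit_is_half():
    """One GT; the top-scored prediction misses, the second is exact:
    the PR staircase holds precision 1/2 at recall 1."""
    gts = [box(0, 0, 5, 5)]
    preds = [box(50, 50, 5, 5, 0.9), box(0, 0, 5, 5, 0.4)]
    ds = DetectionSet(preds, ["im", "im"], gts, ["im"])
    assert fx.average_precision(ds) == pytest.approx(0.5)


def test_ap_empty_ground_truth_undefined():
    with pytest.raises(UndefinedMetricError):
        fx.average_precision(DetectionSet([box(0, 0, 1, 1, 0.5)], ["im"], [], []))


def _brute_force_ap(ds, thr=0.5):
    """Independent oracle: evaluate the PR curve point by point, rebuilding
    the greedy matching from scratch for every score-ranked prefix."""
    scores = np.array([b.score for b in ds.pred_boxes])
    order = np.argsort(-scores, kind="stable")
    n_gt = len(ds.gt_boxes)
    prev_recall, ap = 0.0, 0.0
    for k in range(1, len(order) + 1):
        chosen = order[:k]
        matched = set()
        tp = 0
        for pi in chosen:
            best, best_gt = 0.0, None
            for gi in range(n_gt):
                if gi in matched or ds.gt_image_ids[gi] != ds.pred_image_ids[pi]:
                    continue
                o = fx.iou(ds.pred_boxes[pi], ds.gt_boxes[gi])
                if o > best:
                    best, best_gt = o, gi
            if best_gt is not None and best >= thr:
                matched.add(best_gt)
                tp += 1
        precision = tp / k
        recall = tp / n_gt
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def random_detection_set(rng):
    n_img = int(rng.integers(1, 3))
    gts, gt_ids, preds, pred_ids = [], [], [], []
    for im in range(n_img):
        for _ in range(int(rng.integers(1, 4))):
            gts.append(box(*rng.uniform(0, 20, 2), *rng.uniform(3, 10, 2)))
            gt_ids.append(f"im{im}")
        for _ in range(int(rng.integers(0, 4))):
            if gts and rng.random() < 0.6:
                g = gts[int(rng.integers(len(gts)))]
                b = box(g.x + rng.uniform(-2, 2), g.y + rng.uniform(-2, 2),
                        g.w, g.h, float(np.round(rng.random(), 2)))
            else:
                b = box(*rng.uniform(0, 25, 2), *rng.uniform(3, 10, 2),
                        float(np.round(rng.random(), 2)))
            preds.append(b)
            pred_ids.append(f"im{im}")
    return DetectionSet(preds, pred_ids, gts, gt_ids)


def test_ap_matches_brute_force_enumeration():
    rng = np.random.default_rng(17)
    for _ in range(200):
        ds = random_detection_set(rng)
        assert fx.average_precision(ds) == pytest.approx(_brute_force_ap(ds), abs=1e-12)


def test_ap_invariant_to_monotone_score_transform():
    rng = np.random.default_rng(18)
    ds = random_detection_set(rng)
    while len(ds.pred_boxes) < 3:
        ds = random_detection_set(rng)
    ap1 = fx.average_precision(ds)
    squashed = [fx.BoundingBox(b.x, b.y, b.w, b.h, b.score ** 3) for b in ds.pred_boxes]
    ds2 = DetectionSet(squashed, ds.pred_image_ids, ds.gt_boxes, ds.gt_image_ids)
    assert fx.average_precision(ds2) == pytest.approx(ap1, abs=1e-12)


# -------------------------------------------------------------------- NME

def test_nme_zero_and_uniform_offset():
    rng = np.random.default_rng(19)
    pts = rng.uniform(10, 90, (68, 2))
    gt = fx.LandmarkSet68(pts)
    assert fx.landmark_nme(gt, gt) == 0.0
    d = 3.7
    pred = fx.LandmarkSet68(pts + np.array([d, 0.0]))
    D = fx.interocular_distance(gt)
    assert fx.landmark_nme(pred, gt) == pytest.approx(d / D, abs=1e-12)


def test_nme_matches_formula_oracle():
    rng = np.random.default_rng(20)
    pts = rng.uniform(10, 90, (68, 2))
    gt = fx.LandmarkSet68(pts)
    pred = fx.LandmarkSet68(pts + rng.normal(0, 2, (68, 2)))
    per_point = np.linalg.norm(pred.points - gt.points, axis=1)
    expected = np.sqrt(np.mean(per_point ** 2)) / fx.interocular_distance(gt)
    assert fx.landmark_nme(pred, gt) == pytest.approx(expected, abs=1e-12)


def test_nme_similarity_invariance():
    rng = np.random.default_rng(21)
    pts = rng.uniform(10, 90, (68, 2))
    gt = fx.LandmarkSet68(pts)
    pred = fx.LandmarkSet68(pts + rng.normal(0, 2, (68, 2)))
    base = fx.landmark_nme(pred, gt)
    th = 0.4
    R = 2.5 * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    shift = np.array([7.0, -4.0])
    gt2 = fx.LandmarkSet68(gt.points @ R.T + shift)
    pred2 = fx.LandmarkSet68(pred.points @ R.T + shift)
    assert fx.landmark_nme(pred2, gt2) == pytest.approx(base, abs=1e-9)


# --------------------------------------------------------------- pose MAE

def test_pose_mae_examples_and_oracle():
    gt = [fx.HeadPose(1, 2, 3), fx.HeadPose(-1, 0, 5)]
    assert fx.pose_mae(gt, gt) == (0, 0, 0, 0)
    biased = [fx.HeadPose(p.pitch + 2, p.roll, p.yaw) for p in gt]
    pitch, roll, yaw, avg = fx.pose_mae(biased, gt)
    assert (pitch, roll, yaw) == (2.0, 0.0, 0.0)
    assert avg == pytest.approx(2 / 3)
    rng = np.random.default_rng(22)
    P = rng.normal(size=(10, 3))
    G = rng.normal(size=(10, 3))
    got = fx.pose_mae([fx.HeadPose(*p) for p in P], [fx.HeadPose(*g) for g in G])
    expected = np.abs(P - G).mean(axis=0)
    assert got[:3] == pytest.approx(tuple(expected), abs=1e-12)
    assert got[3] == pytest.approx(float(expected.mean()), abs=1e-12)
    with pytest.raises(ValueError):
        fx.pose_mae([fx.HeadPose(0, 0, 0)], [])


# -------------------------------------------------------------------- F1

def test_f1_examples():
    assert fx.f1_binary([1, 0, 1], [1, 0, 1]) == 1.0
    # TP=2, FP=1, FN=1
    assert fx.f1_binary([1, 1, 1, 0], [1, 1, 0, 1]) == pytest.approx(4 / 6)
    assert fx.f1_binary([0, 0, 0], [1, 1, 0]) == 0.0
    with pytest.raises(UndefinedMetricError):
        fx.f1_binary([1, 0], [0, 0])


def test_f1_matches_sklearn_oracle():
    from sklearn.metrics import f1_score

    rng = np.random.default_rng(23)
    for _ in range(50):
        g = rng.integers(0, 2, 30)
        if g.sum() == 0:
            g[0] = 1
        p = rng.integers(0, 2, 30)
        assert fx.f1_binary(p, g) == pytest.approx(f1_score(g, p, zero_division=0), abs=1e-12)
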