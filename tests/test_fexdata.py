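"""Fex container: sessions, summaries, ISC, mass-univariate OLS, decoding."""

import numpy as np
import pandas as pd
import pytest

import fexkit as fx
from fexkit.exceptions import CollinearityError
from fexkit.fexdata import AU_COLS, EMOTION_COLS, FEATURE_COLS, FEX_COLUMNS


def small_fex(seed=0, n_videos=4, n_frames=40):
    return fx.make_fex_timeseries(n_videos_per_condition=n_videos,
                                  n_frames=n_frames, seed=seed)


# ---------------------------------------------------------------- plumbing

def test_column_groups_partition_features():
    groups = [fx.FexTable.__dict__[g].fget for g in ()]  # noqa: F841 (doc aid)
    fex = small_fex()
    cols = []
    for g in ("faceboxes", "landmarks", "poses", "aus", "emotions"):
        cols.extend(fex.group(g).columns)
    assert sorted(cols) == sorted(FEATURE_COLS)
    assert len(set(cols)) == len(cols)
    with pytest.raises(ValueError):
        fex.group("gaze")


def test_csv_round_trip_is_bit_stable(tmp_path):
    fex = small_fex(seed=5, n_videos=2, n_frames=10)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    fex.to_csv(p1)
    fx.FexTable.read_csv(p1).to_csv(p2)
    assert p1.read_bytes() == p2.read_bytes()


# ---------------------------------------------------------------- sessions

def test_update_sessions_walkthrough_mapping():
    fex = small_fex()
    renamed = fex.update_sessions({"good_news": "good", "bad_news": "bad"})
    assert set(renamed.sessions.unique()) == {"good", "bad"}
    # empty mapping leaves sessions identical
    assert renamed.update_sessions({}).sessions.equals(renamed.sessions)


def test_update_sessions_merge_preserves_row_counts():
    fex = small_fex()
    counts = fex.sessions.value_counts()
    merged = fex.update_sessions({"good_news": "all", "bad_news": "all"})
    assert (merged.sessions == "all").all()
    assert len(merged) == counts.sum()


# ---------------------------------------------------------------- summary

def test_summary_of_constant_column():
    fex = small_fex()
    df = fex.df.copy()
    df["AU01"] = 0.42
    fex = fx.FexTable(df)
    summ = fex.extract_summary(("mean", "std", "min", "max"))
    assert np.allclose(summ["AU01_mean"], 0.42)
    assert np.allclose(summ["AU01_std"], 0.0)
    assert np.allclose(summ["AU01_min"], 0.42)
    assert np.allclose(summ["AU01_max"], 0.42)


def test_extract_mean_matches_construction():
    fex = small_fex()
    df = fex.df.copy()
    df.loc[df["session"] == "good_news", "AU12"] = 0.9
    df.loc[df["session"] == "bad_news", "AU12"] = 0.1
    fex = fx.FexTable(df)
    means = fex.extract_mean()
    assert isinstance(means, fx.FexTable)
    assert len(means) == 2
    got = means.aus["AU12"].to_numpy()
    assert np.allclose(sorted(got), [0.1, 0.9])


def test_summary_matches_direct_groupby_oracle():
    fex = small_fex(seed=9)
    summ = fex.extract_summary(("mean", "std"))
    for session in fex.sessions.unique():
        sub = fex.df[fex.df["session"] == session]
        for col in ("AU05", "happiness", "Pitch"):
            assert summ.loc[session, f"{col}_mean"] == pytest.approx(
                float(np.mean(sub[col])), abs=1e-12)
            assert summ.loc[session, f"{col}_std"] == pytest.approx(
                float(np.std(sub[col], ddof=1)), abs=1e-12)


# -------------------------------------------------------------------- isc

def _fex_from_series(series_by_session):
    """Minimal FexTable with a chosen happiness series per session."""
    rows = []
    for s, vals in series_by_session.items():
        for t, v in enumerate(vals):
            row = dict.fromkeys(FEX_COLUMNS, 0.0)
            row.update(frame=t, input=s, session=s, happiness=float(v),
                       FaceRectWidth=1.0, FaceRectHeight=1.0, FaceScore=1.0)
            rows.append(row)
    return fx.FexTable(pd.DataFrame(rows)[FEX_COLUMNS])


def test_isc_identical_and_negated_series():
    base = np.sin(np.linspace(0, 6, 30))
    fex = _fex_from_series({"a": base, "b": base, "c": -base})
    m = fex.isc(col="happiness")
    assert m.loc["a", "b"] == pytest.approx(1.0)
    assert m.loc["a", "c"] == pytest.approx(-1.0)
    assert np.allclose(np.diag(m), 1.0)
    assert np.allclose(m.values, m.values.T)


def test_isc_matches_pairwise_correlation_oracle():
    rng = np.random.default_rng(3)
    series = {f"s{i}": rng.normal(size=50) for i in range(3)}
    fex = _fex_from_series(series)
    m = fex.isc(col="happiness", method="pearson")
    for a in series:
        for b in series:
            if a != b:
                r = np.corrcoef(series[a], series[b])[0, 1]
                assert m.loc[a, b] == pytest.approx(r, abs=1e-12)


def test_isc_truncates_unequal_lengths_with_warning():
    rng = np.random.default_rng(4)
    x = rng.normal(size=40)
    fex = _fex_from_series({"long": np.concatenate([x, rng.normal(size=10)]), "short": x})
    with pytest.warns(UserWarning, match="truncating"):
        m = fex.isc(col="happiness")
    assert m.loc["long", "short"] == pytest.approx(1.0)


def test_isc_zero_variance_is_missing_not_zero():
    fex = _fex_from_series({"flat": np.zeros(20), "var": np.arange(20.0)})
    m = fex.isc(col="happiness")
    assert np.isnan(m.loc["flat", "var"])
    assert m.loc["flat", "flat"] == 1.0


def test_isc_spearman_monotone_invariance():
    rng = np.random.default_rng(5)
    x = rng.normal(size=30)
    fex = _fex_from_series({"raw": x, "cubed": x ** 3})
    m = fex.isc(col="happiness", method="spearman")
    assert m.loc["raw", "cubed"] == pytest.approx(1.0)


# ---------------------------------------------------------------- regress

def _two_sample_t(a, b):
    """Pooled-variance two-sample t statistic (closed form)."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    return (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))


def test_regress_contrast_equals_two_sample_t():
    fex = small_fex(seed=6)
    coded = fex.update_sessions({"good_news": 1, "bad_news": -1})
    res = coded.regress(X="sessions", y="aus", fit_intercept=True)
    for au in AU_COLS:
        good = fex.df.loc[fex.sessions == "good_news", au].to_numpy()
        bad = fex.df.loc[fex.sessions == "bad_news", au].to_numpy()
        t_oracle = _two_sample_t(good, bad)
        assert res.tstats.loc["sessions", au] == pytest.approx(t_oracle, abs=1e-10)
    assert res.df == len(fex) - 2


def test_regress_exact_linear_fit():
    fex = small_fex(seed=7)
    df = fex.df.copy()
    df["anger"] = 2.0 * df["AU04"] + 1.0
    res = fx.FexTable(df).regress(X="AU04", y="anger", fit_intercept=True)
    assert res.betas.loc["AU04", "anger"] == pytest.approx(2.0, abs=1e-10)
    assert res.betas.loc["intercept", "anger"] == pytest.approx(1.0, abs=1e-10)
    assert np.abs(res.residuals.to_numpy()).max() < 1e-10


def test_regress_invariants():
    fex = small_fex(seed=8)
    coded = fex.update_sessions({"good_news": 1, "bad_news": -1})
    res = coded.regress(X="sessions", y="emotions")
    mask = res.ses.to_numpy() > 0
    assert np.allclose((res.betas.to_numpy() / res.ses.to_numpy())[mask],
                       res.tstats.to_numpy()[mask])
    # residuals orthogonal to design columns
    design = np.column_stack([np.ones(len(coded)), coded.sessions.astype(float)])
    assert np.abs(design.T @ res.residuals.to_numpy()).max() < 1e-8


def test_regress_rank_deficiency_error():
    fex = small_fex(seed=9)
    df = fex.df.copy()
    df["AU02"] = df["AU01"]
    with pytest.raises(CollinearityError):
        fx.FexTable(df).regress(X=["AU01", "AU02"], y="emotions")


def test_regress_null_false_positive_rate():
    """Type-I error calibration: outcomes independent of the design give
    p < 0.05 about 5% of the time (500 simulated outcomes, seed 3)."""
    rng = np.random.default_rng(3)
    n = 60
    hits = total = 0
    while total < 500:
        fex = small_fex(seed=int(rng.integers(1 << 30)), n_videos=2, n_frames=n // 4)
        df = fex.df.copy()
        for c in AU_COLS:
            df[c] = rng.normal(size=len(df))
        coded = fx.FexTable(df).update_sessions({"good_news": 1, "bad_news": -1})
        res = coded.regress(X="sessions", y="aus")
        hits += int((res.pvals.loc["sessions"] < 0.05).sum())
        total += len(AU_COLS)
    rate = hits / total
    assert 0.03 <= rate <= 0.07


def test_regress_bh_adjustment_monotone():
    fex = small_fex(seed=10)
    coded = fex.update_sessions({"good_news": 1, "bad_news": -1})
    res = coded.regress(X="sessions", y="aus", adjust="bh")
    assert res.pvals_adjusted is not None
    assert np.all(res.pvals_adjusted.to_numpy() >= res.pvals.to_numpy() - 1e-12)


# ---------------------------------------------------------------- predict

def test_predict_separable_conditions():
    fex = small_fex(seed=11)
    df = fex.df.copy()
    df.loc[df["session"] == "good_news", "AU12"] = 0.95
    df.loc[df["session"] == "bad_news", "AU12"] = 0.05
    res = fx.FexTable(df).predict(X="aus", y="sessions", folds=4, seed=0)
    assert res.accuracy == 1.0


def test_predict_folds_never_split_a_video():
    fex = small_fex(seed=12)
    res = fex.predict(X="aus", folds=4, seed=1)
    seen = [g for fold in res.fold_groups for g in fold]
    assert sorted(seen) == sorted(fex.inputs.unique())
    flat = [set(fold) for fold in res.fold_groups]
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            assert not (flat[i] & flat[j])


def test_predict_deterministic_under_seed():
    fex = small_fex(seed=13)
    r1 = fex.predict(X="aus", folds=4, seed=5)
    r2 = fex.predict(X="aus", folds=4, seed=5)
    assert r1.accuracy == r2.accuracy
    for a, b in zip(r1.fold_groups, r2.fold_groups):
        assert np.array_equal(a, b)


def test_predict_too_many_folds():
    fex = small_fex(seed=14, n_videos=2)
    with pytest.raises(ValueError, match="folds"):
        fex.predict(X="aus", folds=10)


def test_predict_video_shuffled_labels_are_at_chance():
    """Shuffling session labels at the video level drives grouped-CV accuracy
    to the binomial chance band around 0.5 (20 shuffles)."""
    fex = small_fex(seed=15, n_videos=5, n_frames=30)
    accs = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        df = fex.df.copy()
        vids = sorted(df["input"].unique())
        labels = np.array(["good_news", "bad_news"])[
            rng.permutation(np.arange(len(vids)) % 2)]
        lab_map = dict(zip(vids, labels))
        df["session"] = df["input"].map(lab_map)
        res = fx.FexTable(df).predict(X="aus", folds=5, seed=seed)
        accs.append(res.accuracy)
    mean_acc = float(np.mean(accs))
    # 95% band for the mean of 20 runs around chance, with per-run variance
    # dominated by 10 video assignments
    assert 0.3 <= mean_acc <= 0.7
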