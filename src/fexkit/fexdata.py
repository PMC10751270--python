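"""Frames x features container for facial-expression time series.

A :class:`FexTable` holds one row per video frame with fixed column groups —
face box, 68 landmarks, head pose, 12 action-unit probabilities, 7 emotion
probabilities — plus a ``session`` label per row (by default the input video
identifier).  Sessions drive every statistical method:

* :meth:`FexTable.extract_summary` / :meth:`FexTable.extract_mean` —
  per-session summary statistics of every feature column;
* :meth:`FexTable.isc` — intersubject correlation: the session x session
  matrix of temporal correlations of one feature channel;
* :meth:`FexTable.regress` — mass-univariate OLS: the same design fitted
  independently to every outcome column, returning betas, standard errors,
  t statistics and two-tailed p values with shared degrees of freedom
  (with a +1/-1 session contrast and an intercept this reduces exactly to
  the pooled two-sample t-test);
* :meth:`FexTable.predict` — cross-validated decoding of session labels,
  with folds grouped by input video so that temporally autocorrelated
  frames of one video never straddle a train/test boundary.

The CSV dialect is fixed (see :data:`FEX_COLUMNS`) and round-trips
bit-stably.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps
from sklearn.base import clone as _sk_clone
from sklearn.linear_model import LogisticRegression

from .exceptions import CollinearityError

__all__ = ["FexTable", "RegressionResult", "PredictResult", "FEX_COLUMNS"]

FACEBOX_COLS = ["FaceRectX", "FaceRectY", "FaceRectWidth", "FaceRectHeight", "FaceScore"]
LANDMARK_COLS = [f"x_{i}" for i in range(68)] + [f"y_{i}" for i in range(68)]
POSE_COLS = ["Pitch", "Roll", "Yaw"]
AU_COLS = ["AU01", "AU02", "AU04", "AU05", "AU06", "AU09",
           "AU12", "AU15", "AU17", "AU20", "AU25", "AU26"]
EMOTION_COLS = ["anger", "disgust", "fear", "happiness", "sadness", "surprise", "neutral"]
META_COLS = ["frame", "input"]
FEX_COLUMNS = META_COLS + FACEBOX_COLS + LANDMARK_COLS + POSE_COLS + AU_COLS \
    + EMOTION_COLS + ["session"]

_GROUPS = {
    "faceboxes": FACEBOX_COLS,
    "landmarks": LANDMARK_COLS,
    "poses": POSE_COLS,
    "aus": AU_COLS,
    "emotions": EMOTION_COLS,
}
FEATURE_COLS = FACEBOX_COLS + LANDMARK_COLS + POSE_COLS + AU_COLS + EMOTION_COLS


@dataclass
class RegressionResult:
    """Mass-univariate OLS output; iterable as (b, se, t, p, df, residuals)."""

    betas: pd.DataFrame        # design columns x outcomes
    ses: pd.DataFrame
    tstats: pd.DataFrame
    pvals: pd.DataFrame
    df: int
    residuals: pd.DataFrame    # n x outcomes
    pvals_adjusted: pd.DataFrame | None = None

    def __iter__(self):
        return iter((self.betas, self.ses, self.tstats, self.pvals, self.df, self.residuals))


@dataclass
class PredictResult:
    """Cross-validated decoder; iterable as (model, accuracy)."""

    model: object
    accuracy: float
    fold_accuracies: np.ndarray
    fold_groups: list            # list of arrays of held-out video ids per fold

    def __iter__(self):
        return iter((self.model, self.accuracy))


class FexTable:
    """Wrapper around a pandas DataFrame in the Fex dialect."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in FEX_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"FexTable is missing columns: {missing[:6]}{'...' if len(missing) > 6 else ''}")
        self._df = df.loc[:, FEX_COLUMNS].reset_index(drop=True)

    # -- container plumbing --------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    @property
    def sessions(self) -> pd.Series:
        return self._df["session"]

    @property
    def inputs(self) -> pd.Series:
        return self._df["input"]

    @property
    def aus(self) -> pd.DataFrame:
        return self._df[AU_COLS]

    @property
    def emotions(self) -> pd.DataFrame:
        return self._df[EMOTION_COLS]

    @property
    def poses(self) -> pd.DataFrame:
        return self._df[POSE_COLS]

    @property
    def landmarks(self) -> pd.DataFrame:
        return self._df[LANDMARK_COLS]

    @property
    def faceboxes(self) -> pd.DataFrame:
        return self._df[FACEBOX_COLS]

    def group(self, name: str) -> pd.DataFrame:
        """Select one column group by name ('aus', 'emotions', ...)."""
        if name not in _GROUPS:
            raise ValueError(f"unknown group {name!r}; valid: {sorted(_GROUPS)}")
        return self._df[_GROUPS[name]]

    # -- IO ------------------------------------------------------------------
    @classmethod
    def read_csv(cls, path) -> "FexTable":
        # round_trip parsing keeps write -> read -> write bit-stable
        return cls(pd.read_csv(path, float_precision="round_trip"))

    def to_csv(self, path) -> None:
        self._df.to_csv(path, index=False)

    # -- sessions ------------------------------------------------------------
    def update_sessions(self, mapping: dict) -> "FexTable":
        """Relabel sessions; labels not in the mapping pass through unchanged."""
        new = self._df.copy()
        current = set(new["session"].unique().tolist())
        unused = [k for k in mapping if k not in current]
        if unused:
            warnings.warn(f"session mapping keys not present and ignored: {unused}")
        new["session"] = new["session"].map(lambda s: mapping.get(s, s))
        return FexTable(new)

    # -- summaries -----------------------------------------------------------
    _STATS = {"mean": "mean", "std": "std", "min": "min", "max": "max"}

    def extract_summary(self, stats=("mean",)) -> pd.DataFrame:
        """Per-session summary of every feature column.

        Returns a DataFrame indexed by session with columns
        ``{feature}_{stat}`` (single-stat calls keep the plain feature name).
        """
        bad = [s for s in stats if s not in self._STATS]
        if bad:
            raise ValueError(f"unknown statistics {bad}; valid: {sorted(self._STATS)}")
        if self._df["session"].isna().any():
            raise ValueError("sessions contain missing labels")
        grouped = self._df.groupby("session", sort=True)[FEATURE_COLS]
        pieces = []
        for s in stats:
            agg = grouped.agg(self._STATS[s])
            if len(stats) > 1:
                agg = agg.rename(columns={c: f"{c}_{s}" for c in agg.columns})
            pieces.append(agg)
        return pd.concat(pieces, axis=1)

    def extract_mean(self) -> "FexTable":
        """Per-session means, returned as a one-row-per-session FexTable so
        group selection (``.aus`` etc.) keeps working on the result."""
        means = self.extract_summary(stats=("mean",))
        out = means.reset_index()
        out.insert(0, "frame", 0)
        out.insert(1, "input", out["session"])
        return FexTable(out[FEX_COLUMNS])

    # -- intersubject correlation --------------------------------------------
    def isc(self, col: str, method: str = "pearson") -> pd.DataFrame:
        """Session x session correlation matrix of one feature channel.

        Series are ordered by frame within session and truncated to the
        shortest series (with a warning).  Zero-variance series produce
        missing (NaN) off-diagonal entries; the diagonal is 1 by convention.
        """
        if col not in FEATURE_COLS:
            raise ValueError(f"unknown feature column {col!r}")
        if method not in ("pearson", "spearman"):
            raise ValueError("method must be 'pearson' or 'spearman'")
        labels = sorted(self._df["session"].unique().tolist(), key=str)
        if len(labels) < 2:
            raise ValueError("isc requires at least 2 sessions")
        series = {}
        for s in labels:
            sub = self._df[self._df["session"] == s].sort_values("frame")
            v = sub[col].dropna().to_numpy(dtype=float)
            series[s] = v
        n_min = min(len(v) for v in series.values())
        if n_min < 3:
            raise ValueError("each session needs a series of length >= 3")
        if len({len(v) for v in series.values()}) > 1:
            warnings.warn(f"sessions have unequal lengths; truncating to {n_min} frames")
        mat = pd.DataFrame({s: v[:n_min] for s, v in series.items()})
        corr = mat.corr(method=method)
        np.fill_diagonal(corr.values, 1.0)
        return corr

    # -- mass-univariate regression -------------------------------------------
    def regress(self, X="sessions", y="aus", fit_intercept: bool = True,
                adjust: str | None = None) -> RegressionResult:
        """OLS of every outcome column on a shared design.

        ``X="sessions"`` uses the (numeric) session labels as a regressor —
        the contrast-code idiom where sessions were relabeled to +1/-1.
        ``adjust="bh"`` adds Benjamini-Hochberg adjusted p values.
        """
        if isinstance(X, str) and X == "sessions":
            try:
                xv = self._df["session"].astype(float).to_numpy()
            except (TypeError, ValueError) as e:
                raise ValueError(
                    "X='sessions' requires numeric session codes "
                    "(e.g. update_sessions({'goodNews': 1, 'badNews': -1}))"
                ) from e
            design = xv.reshape(-1, 1)
            xnames = ["sessions"]
        else:
            cols = [X] if isinstance(X, str) else list(X)
            design = self._df[cols].to_numpy(dtype=float)
            xnames = cols
        if isinstance(y, str) and y in _GROUPS:
            Y = self.group(y)
        else:
            ycols = [y] if isinstance(y, str) else list(y)
            Y = self._df[ycols]
        ynames = list(Y.columns)
        Ym = Y.to_numpy(dtype=float)
        if fit_intercept:
            design = np.column_stack([np.ones(len(design)), design])
            xnames = ["intercept"] + xnames
        n, p = design.shape
        if n <= p:
            raise ValueError(f"need n > p for OLS, got n={n}, p={p}")
        rank = np.linalg.matrix_rank(design)
        if rank < p:
            import scipy.linalg as _sl

            _, _, piv = _sl.qr(design, mode="economic", pivoting=True)
            dep = sorted(xnames[j] for j in piv[rank:])
            raise CollinearityError(
                f"design matrix is rank deficient; dependent columns: {dep}", columns=dep
            )
        XtX_inv = np.linalg.inv(design.T @ design)
        beta = XtX_inv @ design.T @ Ym                       # p x m
        resid = Ym - design @ beta
        df = n - p
        sigma2 = (resid ** 2).sum(axis=0) / df               # per outcome
        se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))     # p x m
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        pv = 2.0 * _sps.t.sf(np.abs(t), df)
        mk = lambda a: pd.DataFrame(a, index=xnames, columns=ynames)
        adj = None
        if adjust is not None:
            if adjust != "bh":
                raise ValueError("adjust must be None or 'bh'")
            from statsmodels.stats.multitest import multipletests

            adj_vals = np.empty_like(pv)
            for i in range(pv.shape[0]):
                adj_vals[i] = multipletests(pv[i], method="fdr_bh")[1]
            adj = mk(adj_vals)
        return RegressionResult(
            betas=mk(beta), ses=mk(se), tstats=mk(t), pvals=mk(pv), df=df,
            residuals=pd.DataFrame(resid, columns=ynames),
            pvals_adjusted=adj,
        )

    # -- cross-validated decoding ---------------------------------------------
    def predict(self, X="aus", y: str = "sessions", model=None,
                folds: int = 5, seed: int = 0) -> PredictResult:
        """Decode session labels from features with video-grouped k-fold CV.

        Folds are stratified at the video level: each session class's videos
        are shuffled (``seed``) and dealt round-robin into ``folds`` folds, so
        no video contributes frames to both sides of a split.  The returned
        decoder is refit on all data; its ``coef_`` can be passed to
        :func:`fexkit.facemodel.plot_face` to visualize the decoding axis.
        """
        if y != "sessions":
            raise ValueError("only y='sessions' decoding is supported")
        if isinstance(X, str) and X in _GROUPS:
            Xm = self.group(X).to_numpy(dtype=float)
        else:
            cols = [X] if isinstance(X, str) else list(X)
            Xm = self._df[cols].to_numpy(dtype=float)
        labels = self._df["session"].astype(str).to_numpy()
        groups = self._df["input"].astype(str).to_numpy()
        classes = np.unique(labels)
        if len(classes) < 2:
            raise ValueError("predict requires at least 2 session classes")
        uniq_groups = np.unique(groups)
        if folds > len(uniq_groups):
            raise ValueError(f"folds={folds} exceeds the {len(uniq_groups)} videos available")
        # one label per video (videos are assumed single-session)
        group_label = {g: labels[groups == g][0] for g in uniq_groups}
        rng = np.random.default_rng(seed)
        fold_of = {}
        for c in classes:
            gs = np.array(sorted(g for g in uniq_groups if group_label[g] == c))
            rng.shuffle(gs)
            for i, g in enumerate(gs):
                fold_of[g] = i % folds
        if model is None:
            model = LogisticRegression(max_iter=1000)
        proto = model() if isinstance(model, type) else model
        accs, fold_groups = [], []
        for k in range(folds):
            test_groups = np.array(sorted(g for g in uniq_groups if fold_of[g] == k))
            test_mask = np.isin(groups, test_groups)
            clf = _sk_clone(proto)
            clf.fit(Xm[~test_mask], labels[~test_mask])
            accs.append(float(np.mean(clf.predict(Xm[test_mask]) == labels[test_mask])))
            fold_groups.append(test_groups)
        final = _sk_clone(proto)
        final.fit(Xm, labels)
        accs = np.array(accs)
        return PredictResult(model=final, accuracy=float(accs.mean()),
                             fold_accuracies=accs, fold_groups=fold_groups)
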