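# Methods

This note documents the models implemented in `fexkit`, the parameters that
matter, the synthetic data the package generates for itself, and the limits
of what its tests demonstrate.

## Coordinate and landmark conventions

Pixel coordinates are 0-based with `x` rightward and `y` downward; boxes are
`(x, y, w, h)` from the top-left corner; pixels on a hull boundary count as
inside.  The 68-point landmark scheme is the standard layout: jaw 0–16,
right brow 17–21, left brow 22–26, nose 27–35, right eye 36–41, left eye
42–47, mouth 48–67 (outer lips 48–59, inner lips 60–67).

**Interocular distance** is defined as the Euclidean distance between the
two eye-center means (mean of points 36–41 vs mean of 42–47), *not* the
outer eye corners.  The mean of six points is stable under per-point
annotation jitter, which matters because this distance normalizes every
landmark error the package reports.  It is translation- and
rotation-invariant and scales linearly with the face.

## AU / emotion detection pipeline

The detector is the classical shallow pipeline: standardize a face patch,
extract HOG inside the landmark hull, compress with PCA, classify per AU.

1. **Patch standardization** (`align_crop`): a similarity transform
   (uniform scale + translation, *no rotation*) maps the landmark bounding
   box, expanded 10 % and squared up, onto a `patch_size` × `patch_size`
   patch.  Rotation is deliberately not corrected so that head-rotation
   robustness can be measured rather than silently repaired.
2. **Hull-masked HOG** (`hog_features`): pixels outside the convex hull of
   the 68 transformed landmarks are set to zero *before* gradients are
   computed.  This creates a gradient edge at the hull boundary; that edge
   is the face outline and carries shape information, so it is accepted.
   Defaults: 112 px patch, 8 × 8 px cells, 2 × 2-cell blocks, 8 unsigned
   orientation bins, L2-Hys block normalization → 5 408 features.  These
   are the conventional HOG settings; all are exposed in
   `PreprocessConfig`.
3. **PCA** (`fit_pca`): components are the leading eigenvectors of the
   sample covariance; `k` is the smallest count whose cumulative explained
   variance reaches the retained-variance threshold (default 0.95; at the
   default training size this keeps ≈ 400–450 components).
   `retained_variance=1.0` keeps every non-degenerate component, making
   training-row reconstruction exact.
4. **Per-AU classifiers** (`train_au_detector`): twelve independent binary
   models over {AU1, 2, 4, 5, 6, 9, 12, 15, 17, 20, 25, 26}.  Two
   interchangeable families:
   * *max-margin-linear* — a linear SVM (`C=1`, primal) whose margin is
     mapped to [0, 1] by a Platt-style logistic link fitted on the training
     margins;
   * *gradient-boosted-trees* — XGBoost (150 trees, depth 3, learning rate
     0.2, single-threaded for determinism), which emits calibrated
     probabilities natively.
   Class imbalance is handled by inverse-frequency sample weights.  Binary
   AU calls for F1 scoring threshold the probability at 0.5.
5. **Emotion classifier** (`train_emotion_detector`): a one-vs-rest linear
   SVM over the seven categories with per-class Platt links; the seven
   probabilities are normalized to sum to one.

`fit_detector_bundle` keeps the paper-style default of gradient-boosted
trees.  The synthetic-experiment harness (`train_synth_bundle`) defaults to
the linear variant instead: on the low-texture stylized renders the margin
model is consistently stronger (held-out min per-AU F1 ≈ 0.91–0.95 vs
≈ 0.86 for the trees), an expected behaviour when the informative signal is
a dense linear subspace of PCA scores rather than axis-aligned structure.
Both variants serialize into the same versioned bundle archive, whose bytes
are identical across retrains with the same data and seed (archive
timestamps are fixed; the optional `created` metadata field defaults to
None for exactly this reason).

## Generative face model

`AUFaceModel` is linear: a neutral template `T` (68 points in a normalized
frame — centroid at the origin, interocular distance 1) and a 136 × K
deformation matrix `W`, with `landmarks(a) = T + reshape(W·a)`.  Linearity
gives the three contracts the visualization tools rely on: zero activation
reproduces the template exactly, deformations add, and morphs are affine in
the frame index.  `fit_face_model` estimates `T` and `W` by ordinary least
squares per coordinate (template = mean of all-zero-AU rows when present,
else the regression intercept); the AU design must be full column rank, and
rank deficiency is reported with the names of the dependent columns.
Partial least squares can be swapped in by fitting externally and
constructing the dataclass directly.

The packaged default model covers the 12 detection AUs (plus AU07/AU10/
AU14/AU23 in the extended variant).  Its deformation directions follow
FACS muscle semantics — AU1 raises the inner brows, AU4 lowers and knits
them, AU12 pulls the mouth corners up and out, AU25 parts the lips without
moving the jaw, AU26 drops the jaw, and so on — with magnitudes of roughly
0.05–0.2 interocular units at full activation, chosen so each AU is
visually distinct on the stylized face.  They are an artifact convention,
not measurements of any corpus.  Muscle heatmap anchors (brows for AU1/2/4,
upper lids for 5, cheeks for 6, nose root for 9, mouth corners for
12/15/20, chin for 17/26, lips for 25) are a hand-curated table of
approximate locations.

Rendering rasterizes polylines (jaw, brows, nose) and filled polygons
(eyes, outer and inner mouth) with Pillow at 2× supersampling averaged down
by a box filter — anti-aliased and bit-deterministic.  Heatmaps add a
red-shaded sum of radial Gaussians (σ = 0.18 interocular units) with the
field truncated below 1e-4 so pixels outside the support are untouched.

## Fex container and statistics

`FexTable` is a thin wrapper over a pandas DataFrame in a fixed CSV dialect
(`frame, input, FaceRectX..FaceScore, x_0..y_67, Pitch/Roll/Yaw,
AU01..AU26, anger..neutral, session`); reads use round-trip float parsing
so write → read → write is byte-stable.

* `extract_summary` / `extract_mean`: per-session mean/std/min/max of every
  feature column.
* `isc`: the session × session correlation matrix (Pearson or Spearman) of
  one feature channel, series ordered by frame and truncated to the
  shortest session with a warning.  Zero-variance series yield missing
  entries, never a fabricated 0; the diagonal is 1 by convention.
* `regress`: mass-univariate OLS.  β = (XᵀX)⁻¹Xᵀy per outcome, residual
  variance RSS/(n−p), t = β/SE, two-tailed p from the t distribution with
  n−p df.  With `X="sessions"`, numeric session labels are used directly as
  a regressor — the contrast-code idiom (`update_sessions({"good": 1,
  "bad": -1})`), under which the slope t statistic is algebraically the
  pooled two-sample t.  P values are uncorrected by default with an
  optional Benjamini–Hochberg flag, matching the per-AU reporting style of
  exploratory condition contrasts.  Note the OLS assumes independent rows;
  temporally autocorrelated frames make the per-frame tests anticonservative
  across videos, which is one reason decoding is grouped (below).
* `predict`: k-fold cross-validated decoding of session labels.  Folds are
  stratified *at the video level*: each class's videos are shuffled by the
  seed and dealt round-robin into folds, so frames of one video never
  appear on both sides of a split.  Frame-level folds would exploit the
  strong temporal autocorrelation and report inflated accuracy.  The
  decoder (any scikit-learn classifier; logistic regression by default) is
  refit on all data and returned with its per-fold scores, so its AU
  coefficient vector can be rendered with `plot_face`.

## Metrics and perturbations

* **Average precision**: predictions ranked by descending confidence (ties
  broken by input order, deterministically), greedily matched to the
  highest-IoU unmatched ground-truth box of the same image at IoU ≥ 0.5,
  and the exact precision–recall staircase integrated point by point (no
  interpolation envelope).  The choice is documented so numbers are
  reproducible within this artifact; benchmark tooling elsewhere may
  interpolate differently.
* **Landmark error (NME)**: RMSE over the 68 point-wise Euclidean errors
  divided by the ground-truth interocular distance; invariant under a
  common similarity transform of both shapes.
* **Pose MAE**: per-axis mean absolute error in degrees plus their average.
* **F1**: 2TP/(2TP+FP+FN), 0 when TP = 0, undefined (an error) without
  ground-truth positives.
* **Brightness**: multiply intensities by a factor drawn uniformly from
  [0.1, 0.8] (low) or [1.2, 1.9] (high) and clip to [0, 1]; the factor is
  returned for audit and can be forced for replay.
* **Occlusion**: the tight landmark box of the region (padded 2 px) is set
  to black.  The "eyes" region includes the brows (indices 17–26): the
  brow-raising/lowering muscles sit directly above the eyes and the
  brow-related AUs are exactly the ones an eye mask should lesion.
* **Rotation**: in-plane rotation about the landmark centroid applied with
  one similarity transform to pixels and landmarks.  This is a desk-scale
  stand-in for out-of-plane head rotation and is labeled as such; it probes
  the same failure mode (the detector is trained on upright faces and the
  alignment step does not correct rotation).

## Synthetic data

`make_dataset` draws AU activations (independent Bernoulli occurrences at
p = 0.3 with intensities uniform on [0.5, 1], or uniform emotion prototypes
under `sampling="emotion"`), generates landmarks through the face model,
adds Gaussian landmark jitter (σ = 0.01 interocular units), renders the
stylized face on a 128 px canvas with mild scale (±10 %), placement (±4 %)
and brightness (±10 %) jitter, and stores full ground truth with the
recipe's seed.  Regeneration from the same recipe is byte-identical.

The emotion map restricted to the 12 detection AUs is an EMFACS-style
convention adopted by this package: happiness {6, 12}; sadness {1, 4, 15};
surprise {1, 2, 5, 26}; fear {1, 2, 4, 5, 20, 26}; anger {4, 5, 17};
disgust {9, 15, 25}; neutral = nothing active.

`make_fex_timeseries` emulates the two-condition design: AU channels sit at
the 0.5 maximal-uncertainty baseline, the good-news condition adds +0.15 to
AU06/AU12/AU25, and the temporal noise is AR(1) with coefficient 0.7 and
innovation SD 0.05 — autocorrelated enough that video-grouped
cross-validation is meaningfully harder than frame-level folds.  Emotion
channels are a softmax over prototype-match scores of the AU channels.

**What passing on synthetic data shows — and what it does not.**  The
synthetic faces are line drawings from the package's own generative model:
no texture, identity, demographic variation, out-of-plane pose or lighting
structure of photographs.  End-to-end results (per-AU F1 ≥ 0.9, emotion
macro-F1 ≥ 0.85, robustness *directions* under occlusion/rotation) verify
that the pipeline is implemented correctly and can recover the generator's
structure from pixels; they are not performance claims about photographic
benchmarks.  Robustness findings are asserted as directions only (eye masks
hurt brow/eye AUs more than mouth masks, and vice versa; F1 decays with
rotation), never as magnitudes.

## Problem sizes and numerical choices

Default experiment sizes — 2 000 AU-training faces, 1 400 emotion-training
faces, 400-face held-out test sets, 10 videos × 300 frames per condition,
500 simulated null outcomes — were chosen so the complete test suite and
the acceptance script each run in a few minutes on one CPU while leaving
comfortable statistical margins.  Other numerical conventions: PCA
orthonormality tolerated at 1e-8; probability links clip their argument at
±500 to avoid overflow; degenerate emotion probability rows fall back to
uniform; score ties in AP matching are broken by input order; zero-variance
inputs raise typed errors (`DegenerateDataError`, `DegenerateGeometryError`)
rather than returning silent defaults.

## Known limitations

* The detector requires landmarks as input; no landmark or face detection
  from raw pixels is provided.
* AU outputs are occurrence probabilities, not intensity estimates.
* The linear face model cannot represent non-additive AU interactions
  (e.g. lip funneling vs stretching combinations saturate additively).
* ISC alignment truncates to the shortest series; no time-warping.
* The OLS p values assume exchangeable rows; with autocorrelated frames
  they are exploratory statistics, not confirmatory ones.
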