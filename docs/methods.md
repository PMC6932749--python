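# Methods

## Problem and data model

The pipeline classifies individual cells in early somatic-cell
reprogramming as **iPS progenitors** (fibroblasts that will later form
Oct4-GFP⁺ colonies) or **normal MEFs**, using only numeric feature
tracks: 11 morphology/motion channels per cell per frame (volume, area,
sphericity, ellipsoid prolate/oblate, nucleus–cytoplasm volume ratio,
displacement, speed, intensity StdDev/Max/Min), sampled at a 10-minute
interval. The timeline has three recording phases separated by one-hour
medium changes (18h–24h40min, 25h50min–40h40min, 41h50min–48h40min after
Day 0). Frames are 0-based and global (frame *i* ↔ *i*·10 min); window
endpoints are inclusive, so a 13-frame window starting 19h40min covers
frames 118–130 and ends at 21h40min.

Missingness is a first-class property: a (channel, frame) value may be
absent because segmentation failed at that frame, or because the cell
divided (features of a divided cell are not comparable with its
daughters', so every frame at or after the division frame is masked).
The reader enforces this masking whenever a division frame is known.

## Windowed datasets

A cell enters a window's dataset when its missing window frames — the
union over channels, with division-truncated and out-of-recording frames
counted — do not exceed `max_missing` (default 2). Remaining gaps are
imputed per channel, then the cell flattens to one row in type-major
order (channel 1 frames 1…L, channel 2 frames 1…L, …). Enlarging a
window can therefore only shrink the eligible-cell set.

The standard screening grid (21 start times, 7 per phase; lengths 7–29
odd) contains windows whose tails overrun their phase end by one or two
frames. These are kept by default and the overhang simply surfaces as
missing frames for every cell; a `strict` enumeration mode rejects them
instead.

The 70/30 train/test split is stratified by class with the per-class
training count rounded half-up (`⌊0.7·n + 0.5⌋`), the only rounding rule
consistent with all six published per-phase training counts (78→55,
391→274, 84→59, 420→294, 74→52, 370→259). z-scoring is fitted on the
training partition only and travels with the model (inside a sklearn
`Pipeline`), so holdout and independent evaluations see
training-window parameters; a constant column keeps scale 1 and maps
to 0.

## Imputation

Three imputers fill a gap at window frame *i* from the *originally
observed* frames of the same channel in the same window:

- `set_mean`: mean of all observed window frames;
- `set_mean_mod` (default operating point, with cap 2): unweighted mean
  of the k = 5 nearest observed frames;
- `set_knn`: inverse-square-distance weighted average of those k frames,
  x̂ᵢ = Σⱼ wⱼxⱼ / Σⱼ wⱼ with wⱼ = 1/(i−j)². The weights are normalized —
  an unnormalized sum is not an average and would grow with k.

Numerical conventions: a distance tie for the k-th donor slot admits the
earlier frame; fewer than k donors ⇒ use all; imputed values are never
reused as donors, so multi-gap results are independent of fill order;
all three methods are convex combinations of observed values and
coincide on constant series.

## Classifier and metric

The classifier is an XGBoost gradient-boosted tree ensemble behind a
scikit-learn estimator (`ProgenitorClassifier`), trained single-threaded
with `tree_method="hist"` for determinism, thresholded at 0.5 on the
progenitor probability. The published operating point (learning_rate
0.01, n_estimators 385, gamma 0) is the library default; a light
screening configuration (`FAST_CONFIG`: 40 trees, depth 2, learning_rate
0.3) is used wherever hundreds of fits are needed, since selection and
calibration behavior — not absolute precision at the optimum — is what
those computations measure.

The sole headline metric is precision TP/(TP+FP) with progenitor
positive: experimentalists need the predicted-positive set enriched with
true progenitors. A fold with no predicted positives has undefined
precision; such folds are excluded from averages (with a logged count)
rather than scored 0, because at a 1:5 class ratio empty-positive folds
are a real possibility and scoring them 0 would bias the mean downward.

## Window and feature selection

Window scoring uses repeated stratified 5-fold CV per candidate window.
A start frame qualifies when precision exceeds 0.55 for at least three
successive window lengths; its figure of merit is the mean over its
longest qualifying run (first run on ties). The best length must exceed
0.55 at the best start of every phase and maximizes mean precision, with
smaller across-start standard deviation and then shorter length as tie
breaks.

Step-1 feature selection treats each channel's frames as one bundle and
repeatedly removes the bundle whose removal gives the largest CV
precision, provided that precision *strictly* exceeds the current score
(ties among candidates go to the type later in the canonical order; a
tie with the current score blocks removal). Every score of one
elimination run shares a single CV seed (common random numbers), so the
leave-one-out-versus-current comparison is paired — fold-assignment
noise cancels — and the carried-over accepted score equals what a
recompute would give; accepted scores therefore increase strictly.

Step 2 summarizes each surviving channel as its per-cell window mean,
computes Pearson correlations across cells, and processes pairs with
|r| ≥ 0.60 in descending |r| (ties by member importance): when both
members still survive, the one less important (later in the step-1
importance ranking) is removed. Two channels each strongly correlated
with a common third are thereby both removed while the common channel is
kept, and no surviving pair remains above the threshold. The ≥
comparison is inclusive, and which member of a pair falls is decided by
step-1 importance — both conventions are recorded here because either
could plausibly be reversed.

With per-phase step-1 outputs, pruning runs per phase; drivers report
per-phase sets plus their intersection (union available).

## Validation protocols

- **Cross-validation**: stratified 5-fold, reshuffled and reseeded per
  repeat.
- **Neighbor-window holdout**: one model per repeat is trained on window
  i…j over the training cells and evaluated on windows shifted by −3…+3
  frames (±10 min per step) assembled from held-out cells; train and
  test tables must be disjoint by cell id. The training partition is
  fixed, so repeats differ by booster seed. Offsets leaving the phase
  are skipped with a warning.
- **Independent test**: as holdout, on arbitrary distant windows that
  must share zero frames with (and have the same length as) the training
  window; both enforced.
- The missingness experiment crosses caps 0–5 with the three imputers
  over six windows; at cap 0 all methods coincide by construction. The
  window-selection experiment composes grid scoring with the two
  best-window rules.

Every report carries its per-run precisions, seed and a configuration
snapshot; means and standard deviations are recomputable from the list.

## Synthetic track generator

The generator emulates Imaris-style track exports from this assay: a 1:5
progenitor:MEF ratio (default 80/400), the three-phase 10-minute
timeline, and per-cell feature trajectories. Each channel follows a
stationary AR(1) process around its class mean, x_t = μ + ρ(x_{t−1} − μ)
+ ε_t with ε_t ∼ N(0, σ²(1−ρ²)) and ρ = 0.8, so marginals are N(μ, σ²)
at every frame while trajectories are smooth — which is what makes
window-length effects testable. Innovation vectors are correlated across
channels with a fixed, class-independent block (sphericity–area 0.77,
sphericity–E-prolate 0.66, area–E-prolate 0.55, volume–area 0.50,
displacement–speed 0.70, I-StdDev–I-Max 0.35, E-oblate–volume 0.30):
geometry channels extracted from 2-D images under a constant-thickness
assumption are strongly interdependent, displacement per frame is
essentially speed times the interval, and this is precisely the
structure that makes correlation pruning a meaningful step. Without it,
every discriminative channel is fully redundant given the others and
step-1 elimination may drop any one of them at no cost.

Two separate missingness mechanisms: division — first success of a
per-frame Bernoulli hazard (baseline 0.001/frame, ≈ 17 % of MEFs divide
during the recording), truncating the tail; daughters are not
instantiated — and i.i.d. per-(channel, frame) dropout (default 0.002,
so a 13-frame window loses ≈ 0.3 frames per cell on average and the
cap-2 rule keeps most cells while still exercising the imputers).
The recording is simulated continuously over the full frame span; phase
spans are timeline metadata for the windowing rules, not gaps in the
signal.

`effect_preset(strength)` separates the class means by `strength`·σ on
the four discriminative channels — progenitors higher on
nucleus–cytoplasm ratio and sphericity, lower on area and intensity
StdDev (a more uniform intensity distribution) — and leaves the rest
equal. At strength 0 the two class profiles are identical, giving an
exchangeable null; for strength > 0 the progenitor division hazard
scales up as baseline·(1+strength), reflecting their higher
proliferation rate. Presets: `null` (0), `weak` (1), `strong` (2).

What passing tests on this generator do **not** show: real tracks have
non-Gaussian, non-stationary features, batch/field effects (fields are
simulated as an attribute only), missingness that is correlated with
cell state beyond division, and effect sizes that are unknown and
surely smaller than the strong preset. Synthetic results validate the
machinery and its calibration, not expected performance on microscopy
data; the published precision figures depend on the original unreleased
dataset and are deliberately not targets here.

## Problem sizes and determinism

Screening-scale computations use the light booster and reduced repeat
counts (e.g. repeats 2–3 of 5-fold CV for calibration and elimination
studies, 10 seeded replicates for stochastic claims); these sizes are
the package's chosen defaults for its own studies and are stated
alongside each result. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; booster fits are single-threaded, so
entire experiment grids are bit-reproducible for a given seed.

## Known limitations

- The three imputers are the only missing-data treatments; no
  model-based imputation.
- Per-frame (as opposed to per-bundle) feature elimination is out of
  scope, as are classifiers other than the boosted-tree ensemble.
- Correlation pruning keys on the step-1 importance ranking; with very
  noisy importance estimates the kept member of a correlated pair can
  vary between runs.
- The grid-search ranges for the booster (bracketing the published
  optimum) are a package choice; the original tuning ranges are
  unpublished.
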