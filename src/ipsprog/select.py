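"""Best-window selection rules and two-step feature-type selection.

Window selection scores every candidate window by repeated-CV precision,
keeps start frames whose precision stays above a threshold for at least
three successive window lengths, and picks the window length that clears
the threshold at the best start of every phase with the highest mean
precision (ties: smaller spread, then shorter window).

Feature selection treats each feature type's frames as one bundle.
Step 1 is recursive bundle elimination: repeatedly drop the type whose
removal raises CV precision the most, while it raises it at all.  Step 2
prunes strongly Pearson-correlated survivors (|r| >= 0.60), keeping the
more important member of each pair; two types both strongly correlated
with a common third are thereby both removed and the common type kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import EmptyDatasetError, SelectionError, TrainingError
from .impute import ImputationPolicy
from .model import FAST_CONFIG, ModelConfig, cv_precision
from .tracks import FEATURE_TYPES, TrackTable
from .windows import TimeWindow, WindowDataset, assemble_dataset

PRECISION_THRESHOLD = 0.55
CORRELATION_THRESHOLD = 0.60


# --------------------------------------------------------------------------
# window scoring and the best-window rules
# --------------------------------------------------------------------------

@dataclass
class WindowScoreGrid:
    """Mean CV precision per (start time, window length).

    ``precision`` is starts x lengths; NaN marks a window with
    insufficient data (e.g. a single class present).
    """

    precision: pd.DataFrame
    repeats: int
    cv_folds: int
    phases: dict[int, int] = field(default_factory=dict)  # start time -> phase

    @property
    def starts(self) -> list[int]:
        return list(self.precision.index)

    @property
    def lengths(self) -> list[int]:
        return list(self.precision.columns)


def score_windows(
    tracks: TrackTable,
    grid: list[TimeWindow],
    policy: ImputationPolicy = ImputationPolicy(),
    model_cfg: ModelConfig = FAST_CONFIG,
    repeats: int = 20,
    folds: int = 5,
    seed: int = 0,
    types=FEATURE_TYPES,
) -> WindowScoreGrid:
    """Mean repeated-CV precision for every window of ``grid``.

    Windows whose dataset is empty or single-class are marked NaN
    ("insufficient") rather than scored.  Reproducible from ``seed``:
    each window's sub-seed is derived from its grid position.
    """
    starts = sorted({w.start_time for w in grid})
    lengths = sorted({w.length for w in grid})
    table = pd.DataFrame(np.nan, index=starts, columns=lengths)
    phases = {w.start_time: w.phase for w in grid}
    for w in grid:
        sub_seed = (seed + 7919 * starts.index(w.start_time) + 104729 * lengths.index(w.length)) % (2**31 - 1)
        try:
            ds = assemble_dataset(tracks, w, policy)
        except EmptyDatasetError:
            continue
        if np.unique(ds.y).size < 2:
            continue
        try:
            scores = cv_precision(
                ds.X, ds.y, model_cfg, folds=folds, repeats=repeats, seed=sub_seed
            )
        except (ValueError, TrainingError):
            continue  # too few positives for stratified folds
        if not np.all(np.isnan(scores)):
            table.at[w.start_time, w.length] = float(np.nanmean(scores))
    return WindowScoreGrid(precision=table, repeats=repeats, cv_folds=folds, phases=phases)


def _longest_qualifying_run(row: pd.Series, threshold: float) -> list[int] | None:
    """Longest run of successive lengths with precision above threshold
    (first run on ties); None when the row never qualifies."""
    lengths = list(row.index)
    above = [(not np.isnan(row[l])) and row[l] > threshold for l in lengths]
    best: list[int] = []
    cur: list[int] = []
    for l, ok in zip(lengths, above):
        cur = cur + [l] if ok else []
        if len(cur) > len(best):
            best = list(cur)
    return best or None


def candidate_start_frames(
    grid: WindowScoreGrid,
    threshold: float = PRECISION_THRESHOLD,
    min_run: int = 3,
) -> list[tuple[int, float]]:
    """Start times whose precision exceeds ``threshold`` for at least
    ``min_run`` successive window lengths.

    Each candidate carries the mean precision over its longest
    qualifying run of lengths.
    """
    out = []
    for start in grid.starts:
        run = _longest_qualifying_run(grid.precision.loc[start], threshold)
        if run is not None and len(run) >= min_run:
            out.append((start, float(grid.precision.loc[start, run].mean())))
    return out


def best_start_per_phase(
    grid: WindowScoreGrid,
    candidates: list[tuple[int, float]],
) -> dict[int, int]:
    """Highest-mean candidate start per phase (phases with no candidate
    are absent from the result)."""
    best: dict[int, tuple[int, float]] = {}
    for start, mean in candidates:
        phase = grid.phases.get(start)
        if phase is None:
            continue
        if phase not in best or mean > best[phase][1]:
            best[phase] = (start, mean)
    return {p: s for p, (s, _) in sorted(best.items())}


def best_window_length(
    grid: WindowScoreGrid,
    best_starts: list[int],
    threshold: float = PRECISION_THRESHOLD,
) -> int:
    """The window length clearing ``threshold`` at *all* best starts with
    the highest mean precision (ties: smaller sd across starts, then
    shorter length)."""
    sub = grid.precision.loc[list(best_starts)]
    qualifying = [
        l for l in grid.lengths
        if (~sub[l].isna()).all() and (sub[l] > threshold).all()
    ]
    if not qualifying:
        raise SelectionError(
            "no window length clears the threshold at every best start; "
            f"score grid:\n{sub.to_string()}"
        )
    # max mean, then min sd, then shortest
    key = lambda l: (-sub[l].mean(), sub[l].std(ddof=1), l)
    return min(qualifying, key=key)


# --------------------------------------------------------------------------
# step 1: recursive bundle elimination
# --------------------------------------------------------------------------

@dataclass
class SelectionTrace:
    """Audit trail of the two-step feature selection."""

    initial_score: float
    elimination_order: list[tuple[str, float]]  # (removed type, accepted score)
    candidate_scores: list[dict[str, float]]    # per-iteration leave-one-out scores
    final_types: tuple[str, ...]
    final_score: float
    step2_removed: list[tuple[str, str, float]] = field(default_factory=list)
    # (removed type, correlated-with type, |r|)


def _mean_cv(dataset: WindowDataset, types, cfg, repeats, folds, seed) -> float:
    ds = dataset.select_types(types)
    scores = cv_precision(ds.X, ds.y, cfg, folds=folds, repeats=repeats, seed=seed)
    return float(np.nanmean(scores)) if not np.all(np.isnan(scores)) else float("nan")


def recursive_eliminate(
    dataset: WindowDataset,
    types=None,
    model_cfg: ModelConfig = FAST_CONFIG,
    repeats: int = 20,
    folds: int = 5,
    seed: int = 0,
) -> SelectionTrace:
    """Recursive bundle elimination over feature types.

    Score the current set by repeated-CV precision; for each type, score
    the set without it ("unimportance score"); remove the type with the
    largest such score provided it *strictly* exceeds the current score
    (ties among removal candidates go to the type later in the canonical
    order); repeat until no removal improves or one type remains.
    """
    types = tuple(types or dataset.feature_types)
    if len(types) < 2:
        raise SelectionError("need at least 2 feature types to eliminate")
    if len(dataset.y) < folds:
        raise SelectionError("dataset too small for the requested folds")
    rng = np.random.default_rng(seed)
    # common random numbers: every score of the whole elimination shares
    # one CV seed, so comparisons are paired (fold noise cancels) and the
    # carried-over accepted score equals what a recompute would give
    cv_seed = int(rng.integers(2**31 - 1))
    current = list(types)
    score = _mean_cv(dataset, current, model_cfg, repeats, folds, cv_seed)
    initial = score
    order: list[tuple[str, float]] = []
    candidates_log: list[dict[str, float]] = []
    while len(current) > 1:
        loo = {
            t: _mean_cv(
                dataset,
                [u for u in current if u != t],
                model_cfg,
                repeats,
                folds,
                cv_seed,
            )
            for t in current
        }
        candidates_log.append(dict(loo))
        finite = [v for v in loo.values() if np.isfinite(v)]
        if not finite or not np.isfinite(score):
            break  # no defined precision anywhere: nothing to compare
        best_score = max(finite)
        if not best_score > score:
            break
        # ties -> the type later in the dataset's type order (deterministic;
        # the canonical 11-type order for real datasets)
        tied = [t for t in current if np.isfinite(loo[t]) and loo[t] == best_score]
        victim = max(tied, key=types.index)
        current.remove(victim)
        order.append((victim, best_score))
        score = best_score
    return SelectionTrace(
        initial_score=initial,
        elimination_order=order,
        candidate_scores=candidates_log,
        final_types=tuple(current),
        final_score=score,
    )


class RecursiveBundleEliminator(BaseEstimator, TransformerMixin):
    """sklearn wrapper over :func:`recursive_eliminate`.

    Columns of X must be type-major bundles of ``window_length`` frames
    per entry of ``feature_types``.  After ``fit``, ``retained_types_``
    and ``trace_`` hold the outcome; ``transform`` keeps the retained
    bundles' columns.
    """

    def __init__(
        self,
        feature_types=FEATURE_TYPES,
        window_length: int = 13,
        model_cfg: ModelConfig = FAST_CONFIG,
        repeats: int = 5,
        folds: int = 5,
        random_state: int = 0,
    ):
        self.feature_types = feature_types
        self.window_length = window_length
        self.model_cfg = model_cfg
        self.repeats = repeats
        self.folds = folds
        self.random_state = random_state

    def _as_dataset(self, X, y) -> WindowDataset:
        X = np.asarray(X, dtype=float)
        types = tuple(self.feature_types)
        if X.shape[1] != len(types) * self.window_length:
            raise ValueError(
                f"X has {X.shape[1]} columns; expected "
                f"{len(types)} types x {self.window_length} frames"
            )
        return WindowDataset(
            X=X,
            y=np.asarray(y),
            cell_ids=[str(i) for i in range(len(X))],
            window=TimeWindow(0, self.window_length),
            feature_types=types,
        )

    def fit(self, X, y):
        ds = self._as_dataset(X, y)
        self.trace_ = recursive_eliminate(
            ds,
            model_cfg=self.model_cfg,
            repeats=self.repeats,
            folds=self.folds,
            seed=self.random_state,
        )
        self.retained_types_ = self.trace_.final_types
        self.n_features_in_ = X.shape[1]
        cols = [
            np.arange(i * self.window_length, (i + 1) * self.window_length)
            for i, t in enumerate(self.feature_types)
            if t in self.retained_types_
        ]
        self.support_ = np.concatenate(cols)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.support_]


# --------------------------------------------------------------------------
# step 2: correlation pruning
# --------------------------------------------------------------------------

def type_correlation(dataset: WindowDataset, types=None) -> pd.DataFrame:
    """Pearson correlation between feature types across cells.

    Each type is summarized per cell as its mean over the window frames;
    a zero-variance summary yields 0 coefficients with a warning.
    """
    types = tuple(types or dataset.feature_types)
    if len(dataset.y) < 3:
        raise SelectionError("need at least 3 cells for correlations")
    summary = np.column_stack(
        [dataset.X[:, dataset.type_columns(t)].mean(axis=1) for t in types]
    )
    sds = summary.std(axis=0)
    corr = np.eye(len(types))
    with np.errstate(invalid="ignore"):
        full = np.corrcoef(summary, rowvar=False)
    for i in range(len(types)):
        for j in range(len(types)):
            if i == j:
                continue
            if sds[i] == 0 or sds[j] == 0:
                warnings.warn(
                    f"zero-variance summary for {types[i]} or {types[j]}; "
                    "coefficient recorded as 0",
                    stacklevel=2,
                )
                corr[i, j] = 0.0
            else:
                corr[i, j] = full[i, j]
    return pd.DataFrame(corr, index=list(types), columns=list(types))


def correlation_prune(
    corr: pd.DataFrame,
    types,
    importance_rank,
    threshold: float = CORRELATION_THRESHOLD,
) -> tuple[tuple[str, ...], list[tuple[str, str, float]]]:
    """Drop the less important member of every strongly correlated pair.

    Pairs with |r| >= threshold are processed in descending |r| (ties
    broken by importance of their members); when both members still
    survive, the one later in ``importance_rank`` is removed.  Two types
    each strongly correlated with a common third are thus both removed
    while the common, more important type is kept.  Returns the
    surviving types (canonical order) and the removal log.
    """
    types = [t for t in types]
    rank = {t: i for i, t in enumerate(importance_rank)}
    missing = [t for t in types if t not in rank]
    if missing:
        raise SelectionError(f"importance rank lacks types {missing}")
    pairs = []
    for i, a in enumerate(types):
        for b in types[i + 1:]:
            r = float(corr.at[a, b])
            if abs(r) >= threshold:
                hi, lo = (a, b) if rank[a] < rank[b] else (b, a)
                pairs.append((abs(r), rank[hi], rank[lo], hi, lo, r))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    surviving = set(types)
    removed: list[tuple[str, str, float]] = []
    for _, _, _, hi, lo, r in pairs:
        if hi in surviving and lo in surviving:
            surviving.remove(lo)
            removed.append((lo, hi, r))
    final = tuple(t for t in FEATURE_TYPES if t in surviving) or tuple(
        t for t in types if t in surviving
    )
    return final, removed


class CorrelationPruner(BaseEstimator, TransformerMixin):
    """sklearn wrapper over per-type correlation pruning.

    ``importance_rank`` orders types most to least important (e.g. the
    reverse elimination order of step 1 with survivors first).
    """

    def __init__(
        self,
        feature_types=FEATURE_TYPES,
        window_length: int = 13,
        importance_rank=None,
        threshold: float = CORRELATION_THRESHOLD,
    ):
        self.feature_types = feature_types
        self.window_length = window_length
        self.importance_rank = importance_rank
        self.threshold = threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        types = tuple(self.feature_types)
        ds = WindowDataset(
            X=X,
            y=np.asarray(["?"] * len(X)),
            cell_ids=[str(i) for i in range(len(X))],
            window=TimeWindow(0, self.window_length),
            feature_types=types,
        )
        corr = type_correlation(ds, types)
        rank = list(self.importance_rank or types)
        self.retained_types_, self.removed_ = correlation_prune(
            corr, types, rank, self.threshold
        )
        self.correlation_ = corr
        cols = [
            np.arange(i * self.window_length, (i + 1) * self.window_length)
            for i, t in enumerate(types)
            if t in self.retained_types_
        ]
        self.support_ = np.concatenate(cols)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.support_]


def importance_rank_from_trace(trace: SelectionTrace) -> list[str]:
    """Most-to-least important types implied by an elimination trace.

    Survivors come first, ordered by their last leave-one-out score
    (ascending: the larger the precision drop on removal, the more
    important the type), then eliminated types in reverse removal order
    (removed earlier = less important).
    """
    removed = [t for t, _ in trace.elimination_order]
    survivors = [t for t in FEATURE_TYPES if t in trace.final_types]
    if trace.candidate_scores:
        last = trace.candidate_scores[-1]
        survivors.sort(
            key=lambda t: last.get(t, float("inf"))
        )
    return survivors + list(reversed(removed))
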