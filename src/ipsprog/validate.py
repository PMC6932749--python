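"""The three validation protocols and the two grid experiments.

* repeated stratified cross-validation on one window;
* neighbor-window holdout: a model trained on window i..j of the
  training cells is tested on windows shifted by -3..+3 frames assembled
  from held-out cells (emulating imprecise experiment timing);
* distant-window independent test: the same, on windows sharing zero
  frames with the training window (typically a later phase);
* the missingness x imputation grid and the window-selection grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ProtocolError, SelectionError
from .impute import METHODS, ImputationPolicy
from .model import FAST_CONFIG, ModelConfig, cv_precision, make_pipeline, precision
from .select import (
    WindowScoreGrid,
    best_start_per_phase,
    best_window_length,
    candidate_start_frames,
    score_windows,
)
from .tracks import FEATURE_TYPES, TrackTable
from .windows import TimeWindow, assemble_dataset, enumerate_windows


@dataclass
class ValidationReport:
    """Per-run precisions for one protocol/window, with provenance."""

    protocol: str
    precisions: list[float]
    window: TimeWindow | None
    config: dict
    seed: int
    n_undefined: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.precisions)) if self.precisions else float("nan")

    @property
    def stdev(self) -> float:
        if len(self.precisions) < 2:
            return float("nan")
        return float(np.std(self.precisions, ddof=1))


def _snapshot(cfg: ModelConfig, policy: ImputationPolicy, **extra) -> dict:
    return {
        "model": {
            "learning_rate": cfg.learning_rate,
            "n_estimators": cfg.n_estimators,
            "gamma": cfg.gamma,
            "max_depth": cfg.max_depth,
        },
        "imputation": {
            "method": policy.method,
            "k": policy.k,
            "max_missing": policy.max_missing,
        },
        **extra,
    }


def cross_validate(
    tracks: TrackTable,
    window: TimeWindow,
    types=FEATURE_TYPES,
    policy: ImputationPolicy = ImputationPolicy(),
    cfg: ModelConfig = FAST_CONFIG,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> ValidationReport:
    """Repeated stratified k-fold CV precision on one window's dataset.

    Folds are reshuffled and the booster reseeded per repeat; undefined
    folds (no predicted positives) are dropped from the per-run list and
    counted in ``n_undefined``.
    """
    ds = assemble_dataset(tracks, window, policy, types)
    if np.unique(ds.y).size < 2:
        raise ProtocolError(f"window {window} has a single class")
    scores = cv_precision(ds.X, ds.y, cfg, folds=folds, repeats=repeats, seed=seed)
    defined = [float(s) for s in scores if np.isfinite(s)]
    return ValidationReport(
        protocol="cv",
        precisions=defined,
        window=window,
        config=_snapshot(cfg, policy, folds=folds, repeats=repeats, types=list(types)),
        seed=seed,
        n_undefined=int(np.isnan(scores).sum()),
    )


def holdout_validate(
    tracks_train: TrackTable,
    tracks_test: TrackTable,
    window: TimeWindow,
    offsets=(-3, -2, -1, 0, 1, 2, 3),
    types=FEATURE_TYPES,
    policy: ImputationPolicy = ImputationPolicy(),
    cfg: ModelConfig = FAST_CONFIG,
    repeats: int = 10,
    seed: int = 0,
) -> dict[int, ValidationReport]:
    """Neighbor-window holdout: train on ``window`` over the training
    cells, test on each frame-shifted window over the held-out cells.

    Train/test tables must be disjoint by cell id.  The training-window
    standardization travels with the model.  Offset windows that leave
    the training window's phase are skipped with a warning.
    """
    shared = set(tracks_train.cell_ids) & set(tracks_test.cell_ids)
    if shared:
        raise ProtocolError(f"train and test tables share cells {sorted(shared)[:5]}")
    grid = tracks_train.grid
    train_ds = assemble_dataset(tracks_train, window, policy, types)
    if np.unique(train_ds.y).size < 2:
        raise ProtocolError("training window has a single class")

    test_sets: dict[int, object] = {}
    for off in offsets:
        w = window.shifted(off, grid)
        if w.phase != window.phase:
            warnings.warn(f"offset {off:+d} leaves phase {window.phase}; skipped", stacklevel=2)
            continue
        test_sets[off] = assemble_dataset(tracks_test, w, policy, types)

    rng = np.random.default_rng(seed)
    per_offset: dict[int, list[float]] = {off: [] for off in test_sets}
    undefined: dict[int, int] = {off: 0 for off in test_sets}
    for _ in range(repeats):
        pipe = make_pipeline(cfg, seed=int(rng.integers(2**31 - 1)))
        pipe.fit(train_ds.X, train_ds.y)
        for off, ds in test_sets.items():
            p = precision(ds.y, pipe.predict(ds.X))
            if np.isfinite(p):
                per_offset[off].append(float(p))
            else:
                undefined[off] += 1
    return {
        off: ValidationReport(
            protocol="holdout",
            precisions=per_offset[off],
            window=window.shifted(off, grid),
            config=_snapshot(cfg, policy, offset=off, repeats=repeats),
            seed=seed,
            n_undefined=undefined[off],
        )
        for off in test_sets
    }


def independent_test(
    tracks_train: TrackTable,
    tracks_test: TrackTable,
    train_window: TimeWindow,
    test_windows: list[TimeWindow],
    types=FEATURE_TYPES,
    policy: ImputationPolicy = ImputationPolicy(),
    cfg: ModelConfig = FAST_CONFIG,
    repeats: int = 10,
    seed: int = 0,
) -> dict[TimeWindow, ValidationReport]:
    """Distant-window test: like holdout, but on arbitrary windows that
    must share zero frames with the training window (enforced)."""
    grid = tracks_train.grid
    for w in test_windows:
        if w.overlaps(train_window, grid):
            raise ProtocolError(
                f"test window {w} overlaps the training window {train_window}"
            )
        if w.length != train_window.length:
            raise ProtocolError(
                f"test window {w} length differs from the training window "
                f"({w.length} vs {train_window.length} frames)"
            )
    train_ds = assemble_dataset(tracks_train, train_window, policy, types)
    if np.unique(train_ds.y).size < 2:
        raise ProtocolError("training window has a single class")
    test_sets = {w: assemble_dataset(tracks_test, w, policy, types) for w in test_windows}

    rng = np.random.default_rng(seed)
    per_w: dict[TimeWindow, list[float]] = {w: [] for w in test_windows}
    undefined = {w: 0 for w in test_windows}
    for _ in range(repeats):
        pipe = make_pipeline(cfg, seed=int(rng.integers(2**31 - 1)))
        pipe.fit(train_ds.X, train_ds.y)
        for w, ds in test_sets.items():
            p = precision(ds.y, pipe.predict(ds.X))
            if np.isfinite(p):
                per_w[w].append(float(p))
            else:
                undefined[w] += 1
    return {
        w: ValidationReport(
            protocol="independent",
            precisions=per_w[w],
            window=w,
            config=_snapshot(cfg, policy, train_window=str(train_window), repeats=repeats),
            seed=seed,
            n_undefined=undefined[w],
        )
        for w in test_windows
    }


def missingness_experiment(
    tracks: TrackTable,
    windows: list[TimeWindow],
    caps=(0, 1, 2, 3, 4, 5),
    methods=METHODS,
    types=FEATURE_TYPES,
    cfg: ModelConfig = FAST_CONFIG,
    repeats: int = 20,
    folds: int = 5,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Missing-frame cap x imputation-method grid of CV precision.

    For every (cap, method), the mean and sd of CV precision over the
    given windows, plus the all-method average — the structure used to
    pick the operating point (cap 2, set_mean_mod).
    """
    mean = pd.DataFrame(np.nan, index=list(caps), columns=list(methods))
    sd = pd.DataFrame(np.nan, index=list(caps), columns=list(methods))
    for cap in caps:
        for method in methods:
            policy = ImputationPolicy(method=method, max_missing=cap)
            vals = []
            for i, w in enumerate(windows):
                rep = cross_validate(
                    tracks, w, types, policy, cfg,
                    folds=folds, repeats=repeats, seed=seed + 31 * i,
                )
                vals.append(rep.mean)
            mean.at[cap, method] = float(np.mean(vals))
            sd.at[cap, method] = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
    mean["all_methods"] = mean[list(methods)].mean(axis=1)
    sd["all_methods"] = sd[list(methods)].mean(axis=1)
    return {"mean": mean, "sd": sd}


def window_selection_experiment(
    tracks: TrackTable,
    start_times,
    lengths,
    policy: ImputationPolicy = ImputationPolicy(),
    cfg: ModelConfig = FAST_CONFIG,
    repeats: int = 20,
    folds: int = 5,
    seed: int = 0,
    threshold: float = 0.55,
    min_run: int = 3,
    types=FEATURE_TYPES,
) -> dict:
    """Score the full window grid, then apply the best-start and
    best-length rules.  Returns the grid, candidates, the best start per
    phase and the selected length (None when no length qualifies)."""
    grid_windows = enumerate_windows(start_times, lengths, tracks.grid)
    score_grid = score_windows(
        tracks, grid_windows, policy, cfg, repeats=repeats, folds=folds, seed=seed, types=types
    )
    candidates = candidate_start_frames(score_grid, threshold=threshold, min_run=min_run)
    best_starts = best_start_per_phase(score_grid, candidates)
    selected = None
    if best_starts:
        try:
            selected = best_window_length(
                score_grid, list(best_starts.values()), threshold=threshold
            )
        except SelectionError:
            selected = None
    return {
        "grid": score_grid,
        "candidates": candidates,
        "best_starts": best_starts,
        "best_length": selected,
    }
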