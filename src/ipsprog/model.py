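"""Gradient-boosted classifier, precision metric and grid search.

The classifier is an XGBoost gradient-boosted tree ensemble behind a
scikit-learn estimator wrapper whose published operating point is
learning_rate 0.01, 385 trees, gamma 0.  Precision — TP / (TP + FP)
with the progenitor class positive — is the pipeline's sole headline
metric: biologists need the *predicted-positive* set enriched with true
progenitors.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y
from xgboost import XGBClassifier

from .errors import ConfigError, TrainingError
from .tracks import MEF, PROGENITOR

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    """Booster hyperparameters (defaults = published operating point)."""

    learning_rate: float = 0.01
    n_estimators: int = 385
    gamma: float = 0.0
    max_depth: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if self.n_estimators < 1:
            raise ConfigError("n_estimators must be >= 1")
        if self.gamma < 0:
            raise ConfigError("gamma must be >= 0")


#: A light booster for screening-scale experiments on one CPU.
FAST_CONFIG = ModelConfig(learning_rate=0.3, n_estimators=40, max_depth=2)

#: Default hyperparameter search grid, bracketing the published optimum.
DEFAULT_SEARCH_GRID: dict[str, list] = {
    "learning_rate": [0.005, 0.01, 0.05, 0.1],
    "n_estimators": [100, 200, 385, 500],
    "gamma": [0.0, 0.1, 1.0],
}


def precision(y_true, y_pred) -> float:
    """TP / (TP + FP) with progenitor positive; NaN when no positives
    are predicted (undefined, to be skipped in fold averages)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos = y_pred == PROGENITOR if y_pred.dtype.kind in "UOS" else y_pred == 1
    true_pos = y_true == PROGENITOR if y_true.dtype.kind in "UOS" else y_true == 1
    tp = int(np.sum(pos & true_pos))
    fp = int(np.sum(pos & ~true_pos))
    if tp + fp == 0:
        return float("nan")
    return tp / (tp + fp)


class ProgenitorClassifier(ClassifierMixin, BaseEstimator):
    """Gradient-boosted tree classifier for progenitor-vs-MEF calls.

    Thin sklearn wrapper over :class:`xgboost.XGBClassifier` that fixes
    the label encoding (progenitor positive), applies a probability
    threshold (default 0.5) and records the training column count so a
    mismatched matrix is refused at prediction time.  Deterministic for
    a given ``random_state`` (single-threaded booster).
    """

    def __init__(
        self,
        learning_rate: float = 0.01,
        n_estimators: int = 385,
        gamma: float = 0.0,
        max_depth: int = 6,
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.learning_rate = learning_rate
        self.n_estimators = n_estimators
        self.gamma = gamma
        self.max_depth = max_depth
        self.threshold = threshold
        self.random_state = random_state

    @classmethod
    def from_config(cls, cfg: ModelConfig, threshold: float = 0.5) -> "ProgenitorClassifier":
        return cls(
            learning_rate=cfg.learning_rate,
            n_estimators=cfg.n_estimators,
            gamma=cfg.gamma,
            max_depth=cfg.max_depth,
            threshold=threshold,
            random_state=cfg.seed,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, ensure_min_samples=2)
        classes = np.unique(y)
        if classes.size < 2:
            raise TrainingError("training data contains a single class")
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        y01 = (np.asarray(y) == PROGENITOR).astype(int) if y.dtype.kind in "UOS" else y
        self._booster = XGBClassifier(
            learning_rate=self.learning_rate,
            n_estimators=self.n_estimators,
            gamma=self.gamma,
            max_depth=self.max_depth,
            random_state=self.random_state,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
        )
        self._booster.fit(X, y01)
        self._string_labels = y.dtype.kind in "UOS"
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "_booster")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise TrainingError(
                f"matrix has {X.shape[1]} columns, model was trained on "
                f"{self.n_features_in_}"
            )
        return self._booster.predict_proba(X)

    def decision_scores(self, X) -> np.ndarray:
        """Progenitor probability per cell."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        pos = self.decision_scores(X) >= self.threshold
        if self._string_labels:
            return np.where(pos, PROGENITOR, MEF)
        return pos.astype(int)

    def score(self, X, y) -> float:
        """Precision on (X, y); NaN when no positives are predicted."""
        return precision(y, self.predict(X))


def make_pipeline(cfg: ModelConfig = ModelConfig(), seed: int | None = None) -> Pipeline:
    """StandardScaler + ProgenitorClassifier pipeline (leak-free z-score)."""
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return Pipeline(
        [("zscore", StandardScaler()), ("booster", ProgenitorClassifier.from_config(cfg))]
    )


def train(dataset, cfg: ModelConfig = ModelConfig()) -> Pipeline:
    """Fit the standardize+boost pipeline on a WindowDataset."""
    pipe = make_pipeline(cfg)
    pipe.fit(dataset.X, dataset.y)
    return pipe


def cv_precision(
    X,
    y,
    cfg: ModelConfig = ModelConfig(),
    folds: int = 5,
    repeats: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Per-fold precisions of repeated stratified k-fold CV.

    Folds are reshuffled per repeat and the booster reseeded; undefined
    folds (no predicted positives) appear as NaN and are skipped by
    callers' nan-aware means, with a debug log of the count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(repeats):
        fold_seed = int(rng.integers(2**31 - 1))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
        for tr, te in skf.split(X, y):
            pipe = make_pipeline(cfg, seed=int(rng.integers(2**31 - 1)))
            pipe.fit(X[tr], y[tr])
            out.append(precision(y[te], pipe.predict(X[te])))
    out = np.array(out)
    n_undef = int(np.isnan(out).sum())
    if n_undef:
        logger.debug("%d/%d folds had no predicted positives", n_undef, out.size)
    return out


def grid_search(
    dataset,
    grid: dict[str, list],
    folds: int = 5,
    repeats: int = 1,
    seed: int = 0,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Exhaustive hyperparameter search by mean CV precision.

    Ties go to the first configuration in lexicographic grid order (the
    order of ``grid``'s keys and value lists).  Returns the winning
    ModelConfig and the full score table.
    """
    if not grid:
        raise ConfigError("empty hyperparameter grid")
    keys = list(grid.keys())
    rows = []
    best: tuple[float, ModelConfig] | None = None
    for combo in product(*(grid[k] for k in keys)):
        cfg = replace(ModelConfig(), **dict(zip(keys, combo)))
        scores = cv_precision(
            dataset.X, dataset.y, cfg, folds=folds, repeats=repeats, seed=seed
        )
        mean = float(np.nanmean(scores)) if not np.all(np.isnan(scores)) else float("nan")
        rows.append({**dict(zip(keys, combo)), "mean_precision": mean})
        if best is None or (np.isfinite(mean) and mean > best[0]):
            best = (mean if np.isfinite(mean) else -np.inf, cfg)
    return best[1], pd.DataFrame(rows)
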