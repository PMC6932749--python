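"""Missing-frame counting and within-window imputation.

Tracking software cannot segment every cell at every frame, and a
division truncates the tail of a track, so a window of a track usually
has gaps.  Three imputers fill a gap at frame ``i`` of a window from the
*originally observed* frames of the same channel in the same window:

``set_mean``
    the mean of all observed window frames;
``set_mean_mod``
    the unweighted mean of the k (default 5) nearest observed frames;
``set_knn``
    the inverse-square-distance weighted average of the k nearest
    observed frames: ``sum_j x_j / (i - j)^2 / sum_j 1 / (i - j)^2``.

Neighbor ties (equidistant left/right frames competing for the k-th
slot) go to the earlier frame; already-imputed values never serve as
neighbors, so results do not depend on imputation order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, CoordinateError, ImputationError

METHODS = ("set_mean", "set_knn", "set_mean_mod")


@dataclass(frozen=True)
class ImputationPolicy:
    """Imputation method plus the per-cell missing-frame cap.

    ``max_missing`` is the largest number of missing window frames (union
    over feature types) a cell may have and still enter a dataset; the
    selected operating point of the pipeline is ``set_mean_mod`` with a
    cap of 2.
    """

    method: str = "set_mean_mod"
    k: int = 5
    max_missing: int = 2

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(f"unknown imputation method {self.method!r}")
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.max_missing < 0:
            raise ConfigError("max_missing must be >= 0")


def count_missing(track, window, feature_type: str, grid=None) -> int:
    """Number of window frames at which ``feature_type`` is unobserved.

    Frames beyond the recording span are missing by definition; a window
    that starts outside the span is a coordinate error.
    """
    grid = grid or getattr(window, "grid", None)
    from .windows import window_frames  # local import to avoid a cycle

    frames = window_frames(window, grid)
    vals = track.values
    n = 0
    for f in frames:
        if f not in vals.index or np.isnan(vals.at[f, feature_type]):
            n += 1
    return n


def _nearest_neighbors(i: int, observed: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k observed frames nearest to ``i``.

    Sorted by (distance, frame index), so an equidistant tie admits the
    earlier frame.  Falls back to all observed frames when fewer than k
    are available.
    """
    order = sorted(observed, key=lambda j: (abs(i - j), j))
    return np.asarray(order[: min(k, len(order))])


def impute_series(series: np.ndarray, policy: ImputationPolicy) -> np.ndarray:
    """Fill the gaps of a 1-D window series (NaN = missing).

    Positions index frames within the window; only originally observed
    values act as donors.  Raises :class:`ImputationError` when nothing
    is observed.
    """
    x = np.asarray(series, dtype=float)
    out = x.copy()
    observed = np.flatnonzero(~np.isnan(x))
    if observed.size == 0:
        raise ImputationError("cannot impute a window with no observed frames")
    gaps = np.flatnonzero(np.isnan(x))
    for i in gaps:
        if policy.method == "set_mean":
            out[i] = x[observed].mean()
        else:
            nbrs = _nearest_neighbors(int(i), observed, policy.k)
            if policy.method == "set_mean_mod":
                out[i] = x[nbrs].mean()
            else:  # set_knn: normalized inverse-square-distance weights
                w = 1.0 / (i - nbrs).astype(float) ** 2
                out[i] = float(np.sum(w * x[nbrs]) / np.sum(w))
    return out


class WindowImputer(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer over (n_samples, n_frames) matrices.

    Each row is one cell's single-channel window series; NaNs are filled
    per :func:`impute_series`.  ``fit`` only validates parameters.
    """

    def __init__(self, method: str = "set_mean_mod", k: int = 5, max_missing: int = 2):
        self.method = method
        self.k = k
        self.max_missing = max_missing

    def _policy(self) -> ImputationPolicy:
        return ImputationPolicy(self.method, self.k, self.max_missing)

    def fit(self, X, y=None):
        self._policy()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D (cells x frames) matrix")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        policy = self._policy()
        X = np.asarray(X, dtype=float)
        return np.vstack([impute_series(row, policy) for row in X])
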