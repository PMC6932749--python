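"""Time-window enumeration, dataset assembly, splitting and z-scoring.

A *time window* is a contiguous run of frames (start time + frame
count); a cell enters a window's dataset when its missing window frames
(union over feature types, division-truncated frames included) do not
exceed the imputation policy's cap; remaining gaps are imputed and the
cell flattens to one row in type-major order (type1 frame1..frameL,
type2 frame1.., ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

from .errors import (
    CoordinateError,
    EmptyDatasetError,
    SelectionError,
    StratificationError,
)
from .impute import ImputationPolicy, impute_series
from .tracks import (
    DEFAULT_GRID,
    FEATURE_TYPES,
    PROGENITOR,
    FrameGrid,
    TrackTable,
    format_time,
    parse_time,
)


@dataclass(frozen=True)
class TimeWindow:
    """A (start time, frame count, phase) slice of the timeline.

    Endpoints are inclusive: a window of length L starting at frame s
    covers frames s .. s+L-1, so a 13-frame window starting at 19h40min
    ends at 21h40min.
    """

    start_time: int
    length: int
    phase: int | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise CoordinateError("window length must be >= 1 frame")

    def start_frame(self, grid: FrameGrid = DEFAULT_GRID) -> int:
        return grid.time_to_frame(self.start_time)

    def frames(self, grid: FrameGrid = DEFAULT_GRID) -> np.ndarray:
        s = self.start_frame(grid)
        return np.arange(s, s + self.length)

    def end_time(self, grid: FrameGrid = DEFAULT_GRID) -> int:
        return self.start_time + (self.length - 1) * grid.interval

    def overlaps(self, other: "TimeWindow", grid: FrameGrid = DEFAULT_GRID) -> bool:
        a, b = self.frames(grid), other.frames(grid)
        return bool(np.intersect1d(a, b).size)

    def shifted(self, offset_frames: int, grid: FrameGrid = DEFAULT_GRID) -> "TimeWindow":
        t = self.start_time + offset_frames * grid.interval
        return TimeWindow(t, self.length, grid.phase_of_time(t))

    def __str__(self) -> str:
        return f"{format_time(self.start_time)}+{self.length}f"


def make_window(start_time, length: int, grid: FrameGrid = DEFAULT_GRID) -> TimeWindow:
    """Build a TimeWindow tagged with the phase containing its start."""
    t = parse_time(start_time)
    return TimeWindow(t, int(length), grid.phase_of_time(t))


# The standard screening grid: 21 start times (7 per phase) x 12 window
# lengths, 252 candidate windows in total.
DEFAULT_START_TIMES: tuple[str, ...] = (
    "18h20min", "18h40min", "19h", "19h20min", "19h40min", "20h", "20h20min",
    "26h10min", "26h30min", "26h50min", "27h10min", "27h30min", "27h50min", "28h10min",
    "42h10min", "42h30min", "42h50min", "43h10min", "43h30min", "43h50min", "44h10min",
)
DEFAULT_WINDOW_LENGTHS: tuple[int, ...] = (7, 9, 11, 13, 15, 17, 19, 21, 23, 25, 27, 29)


def enumerate_windows(
    start_times,
    lengths,
    grid: FrameGrid = DEFAULT_GRID,
    strict: bool = False,
) -> list[TimeWindow]:
    """Cartesian product of start times and lengths as TimeWindows.

    Each window is tagged with the phase containing its start time (a
    start in an inter-phase gap is always an error).  Windows whose tail
    overruns their phase end are kept by default — the standard screening
    grid contains such windows, and the overhang simply surfaces as
    missing frames — or rejected when ``strict`` is set.
    """
    starts = [parse_time(t) for t in start_times]
    lengths = [int(l) for l in lengths]
    if not starts or not lengths:
        raise SelectionError("start-time and length lists must be nonempty")
    out = []
    for t, L in product(starts, lengths):
        phase = grid.phase_of_time(t)
        if phase is None:
            raise CoordinateError(f"start time {format_time(t)} is not inside any phase")
        w = TimeWindow(t, L, phase)
        if w.end_time(grid) > grid.phase_span(phase)[1]:
            if strict:
                raise SelectionError(
                    f"window {w} overruns phase {phase} "
                    f"(ends {format_time(w.end_time(grid))})"
                )
            warnings.warn(f"window {w} overruns phase {phase}; kept", stacklevel=2)
        out.append(w)
    return out


@dataclass
class WindowDataset:
    """Flattened cells x (feature types x window frames) design matrix."""

    X: np.ndarray
    y: np.ndarray  # label strings
    cell_ids: list[str]
    window: TimeWindow
    feature_types: tuple[str, ...]
    standardization: dict | None = None

    @property
    def columns(self) -> list[tuple[str, int]]:
        """(feature type, within-window frame offset) per column, type-major."""
        return [
            (t, f)
            for t in self.feature_types
            for f in range(self.window.length)
        ]

    def type_columns(self, feature_type: str) -> np.ndarray:
        """Column indices of one feature type's bundle."""
        i = self.feature_types.index(feature_type)
        L = self.window.length
        return np.arange(i * L, (i + 1) * L)

    def select_types(self, types) -> "WindowDataset":
        """Sub-dataset restricted to ``types`` (canonical order kept)."""
        types = tuple(t for t in self.feature_types if t in set(types))
        cols = np.concatenate([self.type_columns(t) for t in types])
        return WindowDataset(
            X=self.X[:, cols],
            y=self.y,
            cell_ids=self.cell_ids,
            window=self.window,
            feature_types=types,
            standardization=None,
        )

    @property
    def y01(self) -> np.ndarray:
        """Binary labels with progenitor as the positive class."""
        return (self.y == PROGENITOR).astype(int)


def eligible_mask(
    tracks: TrackTable,
    window: TimeWindow,
    max_missing: int,
    types=FEATURE_TYPES,
) -> np.ndarray:
    """Boolean mask of cells with <= max_missing missing window frames.

    A frame counts missing when *any* requested feature type is
    unobserved there (division-truncated and out-of-span frames
    included).
    """
    grid = tracks.grid
    arr = tracks.values_array()
    lo, hi = grid.frame_span
    frames = window.frames(grid)
    tidx = [FEATURE_TYPES.index(t) for t in types]
    inside = (frames >= lo) & (frames <= hi)
    n_outside = int((~inside).sum())
    block = arr[np.ix_(np.arange(len(tracks)), frames[inside] - lo, tidx)]
    missing_frames = np.isnan(block).any(axis=2).sum(axis=1) + n_outside
    return missing_frames <= max_missing


def assemble_dataset(
    tracks: TrackTable,
    window: TimeWindow,
    policy: ImputationPolicy = ImputationPolicy(),
    types=FEATURE_TYPES,
) -> WindowDataset:
    """Build the flattened per-window dataset under the eligibility cap.

    Cells above the cap are dropped; the remaining gaps are imputed per
    ``policy``; columns are type-major.  Raises
    :class:`EmptyDatasetError` when no cell qualifies.
    """
    types = tuple(types)
    grid = tracks.grid
    arr = tracks.values_array()
    lo, hi = grid.frame_span
    frames = window_frames(window, grid)
    keep = eligible_mask(tracks, window, policy.max_missing, types)
    if not keep.any():
        raise EmptyDatasetError(f"no eligible cells in window {window}")
    tidx = np.array([FEATURE_TYPES.index(t) for t in types])
    n_kept = int(keep.sum())
    L = len(frames)
    # (cells, frames, types) block with out-of-span frames as NaN
    block = np.full((n_kept, L, len(types)), np.nan)
    inside = (frames >= lo) & (frames <= hi)
    block[:, inside, :] = arr[np.ix_(np.flatnonzero(keep), frames[inside] - lo, tidx)]
    for c in range(n_kept):
        for j in range(len(types)):
            col = block[c, :, j]
            if np.isnan(col).any():
                block[c, :, j] = impute_series(col, policy)
    X = block.transpose(0, 2, 1).reshape(n_kept, len(types) * L)
    ids = [cid for cid, k in zip(tracks.cell_ids, keep) if k]
    return WindowDataset(
        X=X,
        y=tracks.labels[keep],
        cell_ids=ids,
        window=window,
        feature_types=types,
    )


def stratified_split(
    tracks: TrackTable, frac: float = 0.7, seed: int = 0
) -> tuple[TrackTable, TrackTable]:
    """Per-class random split into train/test track tables.

    The train share per class is ``frac`` of the class size rounded to
    the nearest integer (half up), which reproduces 78->55, 391->274,
    84->59, 420->294, 74->52 and 370->259 at frac 0.7.
    """
    if not 0 < frac < 1:
        raise StratificationError("frac must be in (0, 1)")
    labels = tracks.labels
    classes = np.unique(labels)
    if classes.size < 2:
        raise StratificationError("both classes must be present")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    ids = np.array(tracks.cell_ids)
    for cls in classes:
        members = ids[labels == cls]
        if members.size == 0:
            raise StratificationError(f"class {cls!r} has no members")
        n_train = int(np.floor(frac * members.size + 0.5))
        train_ids.extend(rng.choice(members, size=n_train, replace=False))
    train_set = set(train_ids)
    test_ids = [i for i in tracks.cell_ids if i not in train_set]
    return tracks.subset(train_ids), tracks.subset(test_ids)


def zscore_fit_apply(
    train: WindowDataset, others: list[WindowDataset] | None = None
) -> tuple[WindowDataset, list[WindowDataset]]:
    """z-score the train dataset; apply its parameters to the others.

    Fit on the training partition only (leak-free convention); a
    constant column keeps scale 1 and maps to 0.  For the source-faithful
    global mode, pool the datasets before calling.
    """
    scaler = StandardScaler().fit(train.X)
    params = {"mean": scaler.mean_.copy(), "scale": scaler.scale_.copy()}
    if np.any(scaler.var_ == 0):
        warnings.warn("constant column(s): scale treated as 1", stacklevel=2)

    def _apply(ds: WindowDataset) -> WindowDataset:
        return WindowDataset(
            X=scaler.transform(ds.X),
            y=ds.y,
            cell_ids=ds.cell_ids,
            window=ds.window,
            feature_types=ds.feature_types,
            standardization=params,
        )

    return _apply(train), [_apply(d) for d in (others or [])]


def window_frames(window: TimeWindow, grid: FrameGrid | None = None) -> np.ndarray:
    """Frame indices covered by ``window`` on ``grid``.

    Errors when the window starts outside the recording span; the tail
    may overhang (those frames are simply missing for every cell).
    """
    grid = grid or DEFAULT_GRID
    lo, hi = grid.span
    if not (lo <= window.start_time <= hi):
        raise CoordinateError(
            f"window {window} starts outside the recording span "
            f"[{format_time(lo)}, {format_time(hi)}]"
        )
    return window.frames(grid)
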