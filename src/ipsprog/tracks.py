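"""Track-table data model, frame/time coordinates and CSV I/O.

The pipeline starts from per-cell, per-frame numeric feature tables as
exported by cell-tracking software (e.g. Imaris "Surpass" statistics):
each segmented cell carries 11 morphology/motion channels sampled every
10 minutes.  Missing entries — segmentation dropouts or post-division
truncation — are first-class citizens of the container.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoordinateError, FormatError, IntegrityError

#: The fixed 11-channel feature vocabulary, in canonical order.
FEATURE_TYPES: tuple[str, ...] = (
    "volume",
    "area",
    "sphericity",
    "ellipsoid_prolate",
    "ellipsoid_oblate",
    "nc_volume_ratio",
    "displacement",
    "speed",
    "intensity_stddev",
    "intensity_max",
    "intensity_min",
)

PROGENITOR = "progenitor"
MEF = "mef"
LABELS = (PROGENITOR, MEF)

_TIME_RE = re.compile(r"^\s*(\d+)\s*h(?:\s*(\d+)\s*min)?\s*$", re.IGNORECASE)


def parse_time(value: int | str) -> int:
    """Parse a time as integer minutes or an ``"HHhMMmin"`` string.

    ``"19h40min"`` -> 1180, ``"26h"`` -> 1560, ``1180`` -> 1180.
    """
    if isinstance(value, (int, np.integer)):
        return int(value)
    s = str(value).strip()
    if s.isdigit():
        return int(s)
    m = _TIME_RE.match(s)
    if m is None:
        raise CoordinateError(f"cannot parse time {value!r}")
    hours = int(m.group(1))
    minutes = int(m.group(2) or 0)
    if minutes >= 60:
        raise CoordinateError(f"minutes >= 60 in {value!r}")
    return hours * 60 + minutes


def format_time(minutes: int) -> str:
    """Inverse of :func:`parse_time`: 1180 -> ``"19h40min"``."""
    h, m = divmod(int(minutes), 60)
    return f"{h}h" if m == 0 else f"{h}h{m}min"


# Recording phases between the three one-hour medium changes, in minutes
# after Day 0: 18h-24h40min, 25h50min-40h40min, 41h50min-48h40min.
DEFAULT_PHASE_SPANS: tuple[tuple[int, int, int], ...] = (
    (1, 1080, 1480),
    (2, 1550, 2440),
    (3, 2510, 2920),
)


@dataclass(frozen=True)
class FrameGrid:
    """Frame/time coordinate system of a recording.

    Frames are 0-based and global: frame ``i`` is at time ``i * interval``
    minutes after Day 0.  ``phase_spans`` are inclusive ``(phase, start,
    end)`` time spans in minutes.
    """

    interval: int = 10
    phase_spans: tuple[tuple[int, int, int], ...] = DEFAULT_PHASE_SPANS

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise CoordinateError("interval must be positive")
        spans = sorted(self.phase_spans, key=lambda s: s[1])
        for (_, a0, a1), (_, b0, b1) in zip(spans, spans[1:]):
            if a1 >= b0:
                raise CoordinateError("phase spans must be disjoint and ordered")
        for _, a0, a1 in spans:
            if a0 > a1:
                raise CoordinateError("phase span start after end")

    # -- coordinates -----------------------------------------------------
    def time_to_frame(self, t: int | str) -> int:
        t = parse_time(t)
        if t < 0:
            raise CoordinateError(f"negative time {t}")
        if t % self.interval != 0:
            raise CoordinateError(
                f"time {t} min is not a multiple of the {self.interval}-min interval"
            )
        return t // self.interval

    def frame_to_time(self, frame: int) -> int:
        if frame < 0:
            raise CoordinateError(f"negative frame {frame}")
        return int(frame) * self.interval

    def phase_of_time(self, t: int | str) -> int | None:
        """Phase id whose span contains time ``t``, or None (e.g. a gap)."""
        t = parse_time(t)
        for phase, start, end in self.phase_spans:
            if start <= t <= end:
                return phase
        return None

    def phase_span(self, phase: int) -> tuple[int, int]:
        for p, start, end in self.phase_spans:
            if p == phase:
                return start, end
        raise CoordinateError(f"unknown phase {phase}")

    # -- span ------------------------------------------------------------
    @property
    def span(self) -> tuple[int, int]:
        """(first, last) recorded time in minutes over all phases."""
        starts = [s for _, s, _ in self.phase_spans]
        ends = [e for _, _, e in self.phase_spans]
        return min(starts), max(ends)

    @property
    def frame_span(self) -> tuple[int, int]:
        lo, hi = self.span
        return self.time_to_frame(lo), self.time_to_frame(hi)

    @property
    def frames(self) -> np.ndarray:
        lo, hi = self.frame_span
        return np.arange(lo, hi + 1)


DEFAULT_GRID = FrameGrid()


@dataclass
class CellTrack:
    """One cell's labeled, possibly gapped feature time series.

    ``values`` is a frame-indexed DataFrame with one column per feature
    type; NaN marks a missing (type, frame) observation.  Frames absent
    from the index are missing for every type.  If ``division_frame`` is
    set, every frame at or beyond it is masked to NaN (features of a
    divided cell are not comparable with its daughters').
    """

    cell_id: str
    field_id: str
    label: str
    values: pd.DataFrame
    division_frame: int | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise FormatError(f"unknown label {self.label!r} for cell {self.cell_id}")
        missing_cols = [t for t in FEATURE_TYPES if t not in self.values.columns]
        if missing_cols:
            raise FormatError(f"cell {self.cell_id} lacks feature columns {missing_cols}")
        extra = [c for c in self.values.columns if c not in FEATURE_TYPES]
        if extra:
            raise FormatError(f"unknown feature columns {extra}")
        self.values = self.values.loc[:, list(FEATURE_TYPES)].astype(float).sort_index()
        self.values.index.name = None
        self.values.columns.name = None
        if self.division_frame is not None:
            self.division_frame = int(self.division_frame)
            self.values.loc[self.values.index >= self.division_frame] = np.nan

    def is_missing(self, feature_type: str, frame: int) -> bool:
        if frame not in self.values.index:
            return True
        return bool(np.isnan(self.values.at[frame, feature_type]))

    @property
    def frames(self) -> np.ndarray:
        return self.values.index.to_numpy()

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


class TrackTable:
    """A collection of :class:`CellTrack` sharing one :class:`FrameGrid`."""

    def __init__(self, tracks: list[CellTrack], grid: FrameGrid = DEFAULT_GRID):
        ids = [t.cell_id for t in tracks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate cell ids {dupes}")
        self.tracks = list(tracks)
        self.grid = grid
        self._array: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def __getitem__(self, cell_id: str) -> CellTrack:
        for t in self.tracks:
            if t.cell_id == cell_id:
                return t
        raise KeyError(cell_id)

    @property
    def cell_ids(self) -> list[str]:
        return [t.cell_id for t in self.tracks]

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.tracks])

    def subset(self, cell_ids) -> "TrackTable":
        wanted = set(cell_ids)
        return TrackTable([t for t in self.tracks if t.cell_id in wanted], self.grid)

    def values_array(self) -> np.ndarray:
        """Dense (n_cells, n_grid_frames, 11) array aligned to the grid.

        NaN everywhere a (cell, frame, type) observation is missing.
        Cached; treat as read-only.
        """
        if self._array is None:
            lo, hi = self.grid.frame_span
            n_frames = hi - lo + 1
            arr = np.full((len(self.tracks), n_frames, len(FEATURE_TYPES)), np.nan)
            for i, track in enumerate(self.tracks):
                idx = track.values.index.to_numpy()
                keep = (idx >= lo) & (idx <= hi)
                arr[i, idx[keep] - lo, :] = track.values.to_numpy()[keep]
            self._array = arr
        return self._array

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame: one row per (cell, frame)."""
        rows = []
        for t in self.tracks:
            block = t.values.reset_index(names="frame")
            block.insert(0, "cell_id", t.cell_id)
            block.insert(1, "field_id", t.field_id)
            block.insert(2, "label", t.label)
            rows.append(block)
        return pd.concat(rows, ignore_index=True)


_META_COLS = ("cell_id", "field_id", "label", "frame")


def read_tracks(
    path,
    grid: FrameGrid = DEFAULT_GRID,
    labels_path=None,
) -> TrackTable:
    """Read a long-format tracks CSV into a :class:`TrackTable`.

    The CSV must carry ``cell_id, field_id, label, frame`` plus one column
    per feature type; blank cells denote missing observations.  Rows for
    the same (cell, frame) are merged; conflicting duplicate values raise
    :class:`IntegrityError`.  ``labels_path`` optionally points to a
    metadata CSV with ``cell_id, label`` and optional ``division_frame``
    / ``field_id`` columns that override the in-table values.
    """
    df = pd.read_csv(path, dtype={"cell_id": str, "field_id": str})
    missing = [c for c in ("cell_id", "frame") if c not in df.columns]
    if missing:
        raise FormatError(f"tracks CSV lacks columns {missing}")
    feature_cols = [c for c in df.columns if c not in _META_COLS]
    unknown = [c for c in feature_cols if c not in FEATURE_TYPES]
    if unknown:
        raise FormatError(f"unknown feature columns {unknown}")
    absent = [c for c in FEATURE_TYPES if c not in feature_cols]
    if absent:
        raise FormatError(f"tracks CSV lacks feature columns {absent}")

    meta = {}
    if labels_path is not None:
        ldf = pd.read_csv(labels_path, dtype={"cell_id": str, "field_id": str})
        if "cell_id" not in ldf.columns or "label" not in ldf.columns:
            raise FormatError("labels CSV needs cell_id and label columns")
        meta = ldf.set_index("cell_id").to_dict("index")
    elif "label" not in df.columns:
        raise FormatError("tracks CSV lacks a label column and no labels CSV given")

    lo, hi = grid.frame_span
    frames = df["frame"].to_numpy()
    if not np.issubdtype(frames.dtype, np.integer):
        if not np.all(frames == frames.astype(int)):
            raise CoordinateError("non-integer frame indices")
        frames = frames.astype(int)
    if frames.min() < lo or frames.max() > hi:
        raise CoordinateError(
            f"frame indices outside the grid span [{lo}, {hi}]"
        )

    tracks = []
    for cell_id, block in df.groupby("cell_id", sort=True):
        # merge duplicate (cell, frame) rows; conflicting values are an error
        vals = block.set_index("frame")[list(FEATURE_TYPES)]
        if vals.index.has_duplicates:
            grouped = vals.groupby(level=0)
            if (grouped.nunique(dropna=True) > 1).to_numpy().any():
                raise IntegrityError(
                    f"conflicting duplicate values for cell {cell_id}"
                )
            vals = grouped.first()
        info = meta.get(cell_id, {})
        label = info.get("label") if info else block["label"].iloc[0]
        field_id = info.get("field_id", block["field_id"].iloc[0] if "field_id" in block else "0")
        division = info.get("division_frame")
        if division is not None and (isinstance(division, float) and np.isnan(division)):
            division = None
        tracks.append(
            CellTrack(
                cell_id=str(cell_id),
                field_id=str(field_id),
                label=str(label),
                values=vals,
                division_frame=None if division is None else int(division),
            )
        )
    return TrackTable(tracks, grid)


def write_tracks(table: TrackTable, path, wide: bool = False) -> None:
    """Write a TrackTable as CSV (long by default, wide optional).

    Long format round-trips through :func:`read_tracks`, preserving
    per-(type, frame) missingness as blank cells.
    """
    df = table.to_frame()
    if wide:
        df = df.pivot_table(
            index=["cell_id", "field_id", "label"],
            columns="frame",
            values=list(FEATURE_TYPES),
            dropna=False,
        )
        df.columns = [f"{t}_f{f}" for t, f in df.columns]
        df = df.reset_index()
    df.to_csv(path, index=False)


def time_to_frame(t: int | str, grid: FrameGrid = DEFAULT_GRID) -> int:
    """Map a time in minutes (or ``"HHhMMmin"``) to its frame index."""
    return grid.time_to_frame(t)


def frame_to_time(frame: int, grid: FrameGrid = DEFAULT_GRID) -> int:
    """Map a frame index back to minutes after Day 0."""
    return grid.frame_to_time(frame)
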