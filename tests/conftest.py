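import numpy as np
import pandas as pd
import pytest

from ipsprog.tracks import FEATURE_TYPES, CellTrack, FrameGrid, TrackTable


@pytest.fixture
def small_grid():
    """A compact two-phase recording: frames 0..9 and 12..19."""
    return FrameGrid(interval=10, phase_spans=((1, 0, 90), (2, 120, 190)))


def build_track(
    cell_id,
    label,
    frames,
    grid=None,
    missing=(),
    division_frame=None,
    seed=0,
    field_id="0",
):
    """A deterministic track with optional (type, frame) blanks."""
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(
        rng.normal(10.0, 1.0, size=(len(frames), len(FEATURE_TYPES))),
        index=list(frames),
        columns=list(FEATURE_TYPES),
    )
    for t, f in missing:
        values.at[f, t] = np.nan
    return CellTrack(cell_id, field_id, label, values, division_frame)


@pytest.fixture
def tiny_table(small_grid):
    """Two fully observed cells over frames 0..9 of phase 1."""
    frames = range(10)
    tracks = [
        build_track("c1", "progenitor", frames, seed=1),
        build_track("c2", "mef", frames, seed=2),
    ]
    return TrackTable(tracks, small_grid)
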