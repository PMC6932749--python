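"""Synthetic labeled cell-track generator.

Emulates the statistical structure of time-lapse track exports from an
early-reprogramming experiment: two cell populations (iPS progenitor
cells vs. normal MEFs) at a ~1:5 ratio, 10-minute frame interval across
three recording phases, smooth per-cell feature trajectories, division-
induced tail truncation and random per-(type, frame) dropout.

Each feature channel of each cell follows a stationary AR(1) process
around its class mean::

    x_t = mu + rho * (x_{t-1} - mu) + eps_t,   eps_t ~ N(0, sd^2 (1 - rho^2))

so the marginal distribution is N(mu, sd^2) at every frame while
trajectories stay temporally correlated (rho defaults to 0.8).  The
innovation vectors are correlated across channels (sphericity, area and
the ellipsoid axes are geometrically linked; displacement tracks
speed), matching the strong between-feature correlations that motivate
the correlation-pruning step downstream.  Division is the first success
of a per-frame Bernoulli hazard; all later frames are missing.  Dropout
is i.i.d. per (type, frame) on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .tracks import (
    DEFAULT_GRID,
    FEATURE_TYPES,
    MEF,
    PROGENITOR,
    CellTrack,
    FrameGrid,
    TrackTable,
)
import pandas as pd

# Baseline per-channel (mean, sd) in Imaris-like units: volumes in um^3,
# areas in um^2, sphericity/ratio dimensionless, displacement/speed in
# um and um/min, intensities in camera counts.
_BASE_PROFILE: dict[str, tuple[float, float]] = {
    "volume": (1500.0, 300.0),
    "area": (320.0, 60.0),
    "sphericity": (0.78, 0.08),
    "ellipsoid_prolate": (12.0, 3.0),
    "ellipsoid_oblate": (8.0, 2.0),
    "nc_volume_ratio": (0.35, 0.08),
    "displacement": (6.0, 2.0),
    "speed": (0.45, 0.12),
    "intensity_stddev": (22.0, 5.0),
    "intensity_max": (180.0, 30.0),
    "intensity_min": (12.0, 4.0),
}

DEFAULT_RHO = 0.8
#: Baseline per-frame division hazard (MEF level).  Over the ~185
#: recorded frames this gives a ~17% chance of dividing at least once.
DEFAULT_HAZARD = 0.001

# Cross-channel correlation of the within-cell fluctuations, shared by
# both classes (it reflects measurement geometry, not cell identity):
# sphericity/area/ellipsoid-prolate are geometrically linked, volume
# tracks area, displacement tracks speed, and the intensity spread
# channels co-move weakly.
_CHANNEL_CORR_PAIRS: dict[tuple[str, str], float] = {
    ("sphericity", "area"): 0.77,
    ("sphericity", "ellipsoid_prolate"): 0.66,
    ("area", "ellipsoid_prolate"): 0.55,
    ("volume", "area"): 0.50,
    ("displacement", "speed"): 0.70,
    ("intensity_stddev", "intensity_max"): 0.35,
    ("ellipsoid_oblate", "volume"): 0.30,
}


def default_channel_corr() -> np.ndarray:
    """The default 11x11 channel correlation matrix (positive definite)."""
    n = len(FEATURE_TYPES)
    idx = {t: i for i, t in enumerate(FEATURE_TYPES)}
    corr = np.eye(n)
    for (a, b), r in _CHANNEL_CORR_PAIRS.items():
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    return corr


def _validate_corr(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    n = len(FEATURE_TYPES)
    if corr.shape != (n, n):
        raise ConfigError(f"channel correlation must be {n}x{n}")
    if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
        raise ConfigError("channel correlation must be symmetric with unit diagonal")
    if np.linalg.eigvalsh(corr).min() <= 0:
        raise ConfigError("channel correlation must be positive definite")
    return corr


@dataclass(frozen=True)
class ClassProfile:
    """Per-class generative parameters: one (mean, sd, rho) per channel
    plus a per-frame division hazard."""

    means: dict[str, float]
    sds: dict[str, float]
    rhos: dict[str, float]
    division_hazard: float = DEFAULT_HAZARD

    def __post_init__(self) -> None:
        for t in FEATURE_TYPES:
            if t not in self.means or t not in self.sds or t not in self.rhos:
                raise ConfigError(f"profile lacks parameters for {t!r}")
            if self.sds[t] <= 0:
                raise ConfigError(f"sd for {t!r} must be > 0")
            if not 0 <= self.rhos[t] < 1:
                raise ConfigError(f"rho for {t!r} must be in [0, 1)")
        if not 0 <= self.division_hazard <= 1:
            raise ConfigError("division hazard must be in [0, 1]")


def _base_class_profile(hazard: float = DEFAULT_HAZARD) -> ClassProfile:
    return ClassProfile(
        means={t: m for t, (m, _) in _BASE_PROFILE.items()},
        sds={t: s for t, (_, s) in _BASE_PROFILE.items()},
        rhos={t: DEFAULT_RHO for t in FEATURE_TYPES},
        division_hazard=hazard,
    )


@dataclass(frozen=True)
class SimConfig:
    """Full simulation configuration (1:5 progenitor:MEF by default)."""

    n_progenitor: int = 80
    n_mef: int = 400
    grid: FrameGrid = DEFAULT_GRID
    dropout_prob: float = 0.002
    profiles: dict[str, ClassProfile] = field(default_factory=dict)
    channel_corr: np.ndarray | None = None
    n_fields: int = 33
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_progenitor < 1 or self.n_mef < 1:
            raise ConfigError("class sizes must be positive")
        if not 0 <= self.dropout_prob < 1:
            raise ConfigError("dropout_prob must be in [0, 1)")
        if not self.profiles:
            base = _base_class_profile()
            object.__setattr__(
                self, "profiles", {PROGENITOR: base, MEF: base}
            )
        for lab in (PROGENITOR, MEF):
            if lab not in self.profiles:
                raise ConfigError(f"missing profile for {lab!r}")
        corr = self.channel_corr if self.channel_corr is not None else default_channel_corr()
        object.__setattr__(self, "channel_corr", _validate_corr(corr))


#: Channels whose class means separate under :func:`effect_preset`, with
#: the sign of the progenitor shift (in units of the channel sd).
EFFECT_DIRECTIONS: dict[str, float] = {
    "nc_volume_ratio": +1.0,  # progenitors: higher nucleus/cytoplasm ratio
    "sphericity": +1.0,       # rounder
    "intensity_stddev": -1.0, # more uniform intensity
    "area": -1.0,             # smaller
}


def effect_preset(strength: float, seed: int = 0, **overrides) -> SimConfig:
    """Config whose class means differ by ``strength``·sd on the four
    discriminative channels.

    strength 0 yields a class-exchangeable null (identical profiles,
    equal hazards); for strength > 0 the progenitor division hazard
    exceeds the MEF hazard, reflecting the higher proliferation rate of
    progenitor cells.
    """
    if strength < 0:
        raise ConfigError("strength must be nonnegative")
    mef = _base_class_profile(hazard=DEFAULT_HAZARD)
    prog_means = dict(mef.means)
    for t, sign in EFFECT_DIRECTIONS.items():
        prog_means[t] = mef.means[t] + sign * strength * mef.sds[t]
    prog = ClassProfile(
        means=prog_means,
        sds=dict(mef.sds),
        rhos=dict(mef.rhos),
        division_hazard=DEFAULT_HAZARD * (1.0 + strength),
    )
    return SimConfig(profiles={PROGENITOR: prog, MEF: mef}, seed=seed, **overrides)


PRESETS = {"null": 0.0, "weak": 1.0, "strong": 2.0}


def preset(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Named presets: null (strength 0), weak (1) and strong (2)."""
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return effect_preset(PRESETS[name], seed=seed, **overrides)


def simulate_tracks(config: SimConfig) -> TrackTable:
    """Draw a labeled :class:`TrackTable` from ``config``.

    Fully reproducible from ``config.seed``.  The recording is simulated
    continuously over the grid's full frame span (phase spans are
    timeline metadata used by the windowing rules, not gaps in the
    simulated signal).
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    lo, hi = grid.frame_span
    frames = np.arange(lo, hi + 1)
    n_frames = frames.size
    chol = np.linalg.cholesky(config.channel_corr)

    tracks = []
    counts = [(PROGENITOR, config.n_progenitor), (MEF, config.n_mef)]
    for label, n_cells in counts:
        prof = config.profiles[label]
        mu = np.array([prof.means[t] for t in FEATURE_TYPES])
        sd = np.array([prof.sds[t] for t in FEATURE_TYPES])
        rho = np.array([prof.rhos[t] for t in FEATURE_TYPES])
        innov_sd = sd * np.sqrt(1.0 - rho**2)
        for i in range(n_cells):
            # cross-channel-correlated standard innovations
            z = rng.normal(size=(n_frames, len(FEATURE_TYPES))) @ chol.T
            x = np.empty((n_frames, len(FEATURE_TYPES)))
            x[0] = mu + sd * z[0]
            for k in range(1, n_frames):
                x[k] = mu + rho * (x[k - 1] - mu) + innov_sd * z[k]
            # division: first Bernoulli(hazard) success truncates the tail
            division_frame = None
            if prof.division_hazard > 0:
                hits = rng.random(n_frames) < prof.division_hazard
                if hits.any():
                    division_frame = int(frames[int(np.argmax(hits))])
            if config.dropout_prob > 0:
                drop = rng.random(x.shape) < config.dropout_prob
                x[drop] = np.nan
            values = pd.DataFrame(x, index=frames, columns=list(FEATURE_TYPES))
            tracks.append(
                CellTrack(
                    cell_id=f"{label}_{i:04d}",
                    field_id=str(rng.integers(config.n_fields)),
                    label=label,
                    values=values,
                    division_frame=division_frame,
                )
            )
    return TrackTable(tracks, grid)
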