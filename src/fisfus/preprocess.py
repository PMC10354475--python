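"""Cleaning of raw GPS fixes and regularization to an exact fixed-interval grid.

The cleaning stages mirror standard practice for high-frequency GPS herd
data: drop positions outside the paddock boundary, drop positions triangulated
from too few satellites, drop positions that the animal could not have reached
at its maximum movement speed, then linearly interpolate every individual onto
a shared grid (default 6 s) while filling only short gaps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .errors import ConfigError, DataError
from .trajectories import TrajectorySet

logger = logging.getLogger("fisfus")

__all__ = [
    "PreprocessConfig",
    "filter_boundary",
    "filter_satellites",
    "filter_speed",
    "exclude_intervals",
    "regularize",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Cleaning and regularization parameters.

    min_satellites
        Fixes triangulated from fewer satellites are dropped (3 is the
        minimum needed for a 2-D position).
    v_max
        Maximum plausible movement speed in m/s; for merino sheep 1.5 m/s
        (measured in a simulated predation event).
    dt
        Output grid spacing in seconds.
    max_gap
        Longest run of consecutive grid steps without raw-fix support that
        is still filled by interpolation.
    boundary
        Optional paddock polygon; fixes outside it are dropped.
    """

    min_satellites: int = 3
    v_max: float = 1.5
    dt: float = 6.0
    max_gap: int = 2
    boundary: Polygon | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.v_max <= 0:
            raise ConfigError("v_max must be positive")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.max_gap < 0:
            raise ConfigError("max_gap must be >= 0")
        if self.min_satellites < 0:
            raise ConfigError("min_satellites must be >= 0")


def filter_boundary(fixes: pd.DataFrame, boundary: Polygon) -> pd.DataFrame:
    """Drop fixes outside the paddock boundary (edge-inclusive).

    Positions exactly on the polygon edge are retained: GPS jitter at fences
    should not delete true positions.
    """
    if boundary.area <= 0:
        raise ConfigError("boundary polygon has zero area")
    pts = shapely.points(fixes["x"].to_numpy(), fixes["y"].to_numpy())
    keep = shapely.covers(boundary, pts)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("boundary filter removed %d fixes", n_removed)
    return fixes[keep].reset_index(drop=True)


def filter_satellites(fixes: pd.DataFrame, min_satellites: int = 3) -> pd.DataFrame:
    """Drop fixes determined with fewer than ``min_satellites`` satellites.

    Fixes lacking a satellite count are retained with a warning.
    """
    if "nsat" not in fixes.columns or fixes["nsat"].isna().all():
        logger.warning("no satellite counts available; satellite filter skipped")
        return fixes.reset_index(drop=True)
    nsat = fixes["nsat"]
    if nsat.isna().any():
        logger.warning(
            "%d fixes lack a satellite count and were retained", int(nsat.isna().sum())
        )
    keep = nsat.isna() | (nsat >= min_satellites)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("satellite filter removed %d fixes", n_removed)
    return fixes[keep].reset_index(drop=True)


def _speed_keep_mask(t: np.ndarray, x: np.ndarray, y: np.ndarray, v_max: float) -> np.ndarray:
    """Iterative spike removal for one individual's track.

    A fix is removed iff it is unreachable (implied speed > v_max) from both
    of its up-to-two nearest preceding retained fixes AND from both of its
    up-to-two nearest following retained fixes. Removal is applied in whole
    passes until a fixpoint, so the result does not depend on scan order.
    """
    keep = np.ones(t.size, dtype=bool)

    def unreachable(i: int, j: int) -> bool:
        dist = math.hypot(x[i] - x[j], y[i] - y[j])
        return dist > v_max * abs(t[i] - t[j])

    while True:
        idx = np.flatnonzero(keep)
        remove: list[int] = []
        for pos, i in enumerate(idx):
            prevs = idx[max(0, pos - 2) : pos]
            nexts = idx[pos + 1 : pos + 3]
            if prevs.size == 0 and nexts.size == 0:
                continue
            if all(unreachable(i, j) for j in prevs) and all(
                unreachable(i, j) for j in nexts
            ):
                remove.append(i)
        if not remove:
            return keep
        keep[remove] = False


def filter_speed(fixes: pd.DataFrame, v_max: float = 1.5) -> pd.DataFrame:
    """Remove positions unreachable at maximum movement speed.

    The test window spans the two previous and two following retained fixes
    of the same individual; removal iterates until stable. A track whose
    every implied consecutive speed is within ``v_max`` is never touched.
    """
    keep_parts = []
    for _, grp in fixes.groupby("id", sort=False):
        t = grp["time"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise DataError(f"non-monotone timestamps for individual {grp['id'].iloc[0]!r}")
        mask = _speed_keep_mask(t, grp["x"].to_numpy(float), grp["y"].to_numpy(float), v_max)
        keep_parts.append(pd.Series(mask, index=grp.index))
    if not keep_parts:
        return fixes.reset_index(drop=True)
    keep = pd.concat(keep_parts).sort_index()
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("speed filter removed %d fixes", n_removed)
    return fixes[keep.to_numpy()].reset_index(drop=True)


def exclude_intervals(fixes: pd.DataFrame, intervals) -> pd.DataFrame:
    """Drop fixes whose time falls in any half-open [start, end) interval.

    Used to mask handling periods (e.g. collar battery changes), which must
    be supplied by the user.
    """
    if not intervals:
        return fixes.reset_index(drop=True)
    t = fixes["time"].to_numpy(dtype=float)
    drop = np.zeros(t.size, dtype=bool)
    for start, end in intervals:
        if end <= start:
            raise ConfigError("exclusion interval must have end > start")
        drop |= (t >= start) & (t < end)
    if drop.any():
        logger.info("excluded %d fixes in masked intervals", int(drop.sum()))
    return fixes[~drop].reset_index(drop=True)


def _default_t0(first_fix_time: float) -> float:
    """First fix time rounded down to a whole minute (grid phase default)."""
    return math.floor(first_fix_time / 60.0) * 60.0


def regularize(
    fixes: pd.DataFrame,
    cfg: PreprocessConfig | None = None,
    t0: float | None = None,
    t_end: float | None = None,
) -> TrajectorySet:
    """Resample cleaned fixes onto the exact ``dt`` grid.

    For every individual and grid step the position is the linear (in time)
    interpolation of the bracketing raw fixes, provided the run of
    consecutive grid steps without raw-fix support containing that step is
    no longer than ``max_gap``. Longer unsupported runs become MISSING.
    Positions are never extrapolated beyond an individual's first or last
    fix; a fix outside the bracketed range still populates its single
    nearest grid step (within half a grid interval), which is what keeps a
    one-fix track from vanishing.

    A grid step is "supported" when at least one raw fix falls within half a
    grid interval of it, which makes the "maximum of ``max_gap`` consecutive
    missing locations" rule operational on the regular grid.
    """
    cfg = cfg or PreprocessConfig()
    if fixes.empty:
        logger.warning("regularize called with an empty fix table")
        return TrajectorySet([], 0.0 if t0 is None else t0, cfg.dt, np.empty((0, 0, 2)))
    if t0 is None:
        t0 = _default_t0(float(fixes["time"].min()))
    if t_end is None:
        t_end = float(fixes["time"].max())
    if t_end <= t0:
        raise ConfigError("t_end must be greater than t0")
    dt = cfg.dt
    n_steps = int(math.floor((t_end - t0) / dt)) + 1
    tau = t0 + np.arange(n_steps) * dt

    ids = sorted(fixes["id"].unique())
    xy = np.full((len(ids), n_steps, 2), np.nan)
    grouped = dict(tuple(fixes.groupby("id", sort=False)))
    for row, ind in enumerate(ids):
        grp = grouped[ind].sort_values("time", kind="mergesort")
        ft = grp["time"].to_numpy(dtype=float)
        fx = grp["x"].to_numpy(dtype=float)
        fy = grp["y"].to_numpy(dtype=float)

        near = np.rint((ft - t0) / dt).astype(int)
        in_grid = (near >= 0) & (near < n_steps)
        close = np.abs(ft - (t0 + near * dt)) <= dt / 2 + 1e-9
        supported = np.zeros(n_steps, dtype=bool)
        supported[near[in_grid & close]] = True

        inside = (tau >= ft[0]) & (tau <= ft[-1])
        px = np.interp(tau, ft, fx)
        py = np.interp(tau, ft, fy)
        present = inside.copy()

        # long unsupported runs become MISSING even where bracketed
        run_id = np.cumsum(np.r_[True, np.diff(supported.astype(int)) != 0])
        for rid in np.unique(run_id[~supported]):
            sel = run_id == rid
            if int(sel.sum()) > cfg.max_gap:
                present[sel] = False

        # a supported step just outside the bracketed range snaps to its fix
        snap = supported & ~inside
        if snap.any():
            for k in np.flatnonzero(snap):
                j = int(np.argmin(np.abs(ft - tau[k])))
                px[k], py[k] = fx[j], fy[j]
            present |= snap

        xy[row, present, 0] = px[present]
        xy[row, present, 1] = py[present]

    return TrajectorySet(ids, t0, dt, xy)


def preprocess(
    fixes: pd.DataFrame,
    cfg: PreprocessConfig | None = None,
    exclude=None,
    t0: float | None = None,
    t_end: float | None = None,
) -> TrajectorySet:
    """Full cleaning pipeline: boundary, satellites, speed, regularize."""
    cfg = cfg or PreprocessConfig()
    if exclude:
        fixes = exclude_intervals(fixes, exclude)
    if cfg.boundary is not None:
        fixes = filter_boundary(fixes, cfg.boundary)
    fixes = filter_satellites(fixes, cfg.min_satellites)
    fixes = filter_speed(fixes, cfg.v_max)
    return regularize(fixes, cfg, t0=t0, t_end=t_end)
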