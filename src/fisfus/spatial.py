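"""Grid-based spatial analysis: occupancy, event counts, occupancy-normalized
event rates, resource distances, correlations and the cell-hour mixed model.

A square grid (default 50 m cells, matching the outer grouping radius) is
laid over the paddock. Raw event counts per cell confound event propensity
with how much the cell is used, so rates are normalized by occupancy (the
number of animal-time-steps spent in the cell), with a minimum-occupancy
filter against small-sample noise. The mixed model relates per-cell-per-hour
event counts to resource distance and hourly activity with a random
intercept per cell.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from scipy.spatial.distance import cdist

from .errors import ConfigError, DataError
from .events import EventList
from .metrics import local_clock, step_displacements
from .trajectories import TrajectorySet

logger = logging.getLogger("fisfus")

__all__ = [
    "Grid",
    "CellStats",
    "occupancy",
    "event_cell_counts",
    "distance_to_resource",
    "normalized_rate",
    "pearson",
    "cell_hour_table",
    "fit_cell_hour_model",
    "MixedModelResult",
]


@dataclass(frozen=True)
class Grid:
    """Axis-aligned square grid; cell (col i, row j) covers the half-open box
    [x0 + i*s, x0 + (i+1)*s) x [y0 + j*s, y0 + (j+1)*s), so a position
    exactly on a boundary belongs to the higher-index cell."""

    x0: float
    y0: float
    cell_size: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ConfigError("cell_size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ConfigError("grid must have at least one cell")

    @classmethod
    def from_bounds(cls, xmin, ymin, xmax, ymax, cell_size: float = 50.0) -> "Grid":
        """Grid anchored at the floor of the bounding box to the cell size."""
        x0 = np.floor(xmin / cell_size) * cell_size
        y0 = np.floor(ymin / cell_size) * cell_size
        n_cols = int(np.floor((xmax - x0) / cell_size)) + 1
        n_rows = int(np.floor((ymax - y0) / cell_size)) + 1
        return cls(float(x0), float(y0), float(cell_size), n_cols, n_rows)

    @classmethod
    def from_traj(cls, traj: TrajectorySet, cell_size: float = 50.0) -> "Grid":
        xy = traj.xy[traj.present()]
        if xy.size == 0:
            raise DataError("cannot build a grid from an all-missing trajectory")
        return cls.from_bounds(
            xy[:, 0].min(), xy[:, 1].min(), xy[:, 0].max(), xy[:, 1].max(), cell_size
        )

    def cell_index(self, x, y):
        """(col, row) of positions; indices may fall outside the grid."""
        col = np.floor((np.asarray(x) - self.x0) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.y0) / self.cell_size).astype(int)
        return col, row

    def inside(self, col, row):
        return (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)

    def centers(self) -> np.ndarray:
        """Cell center coordinates, shape (n_rows, n_cols, 2)."""
        cx = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        cy = self.y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size
        out = np.empty((self.n_rows, self.n_cols, 2))
        out[..., 0] = cx[None, :]
        out[..., 1] = cy[:, None]
        return out


@dataclass
class CellStats:
    """Per-cell layers of one analysis: all arrays are (n_rows, n_cols)."""

    grid: Grid
    occupancy: np.ndarray | None = None
    event_count: np.ndarray | None = None
    event_count_by_hour: np.ndarray | None = None  # (n_rows, n_cols, 24)
    distance: np.ndarray | None = None
    normalized_rate: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.meshgrid(
            np.arange(self.grid.n_rows), np.arange(self.grid.n_cols), indexing="ij"
        )
        data = {"row": rows.ravel(), "col": cols.ravel()}
        for name in ("occupancy", "event_count", "distance", "normalized_rate"):
            layer = getattr(self, name)
            if layer is not None:
                data[name] = layer.ravel()
        return pd.DataFrame(data)


def occupancy(traj: TrajectorySet, grid: Grid) -> tuple[np.ndarray, int]:
    """Animal-time-steps per cell.

    Every present (individual, step) position increments exactly one cell;
    positions outside the grid go to a flagged overflow count.
    """
    xy = traj.xy[traj.present()]
    col, row = grid.cell_index(xy[:, 0], xy[:, 1])
    ok = grid.inside(col, row)
    counts = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
    np.add.at(counts, (row[ok], col[ok]), 1)
    n_overflow = int((~ok).sum())
    if n_overflow:
        logger.warning("%d positions fall outside the grid (overflow bin)", n_overflow)
    return counts, n_overflow


def event_cell_counts(
    events: EventList, grid: Grid, by_hour: bool = False, tz: str = "UTC"
):
    """Located events per cell, optionally stratified by local hour of day.

    Events without a defined location are skipped with a warning; events
    outside the grid are counted in the returned overflow tally.
    Returns ``(counts, n_overflow)`` or ``(counts, by_hour_counts,
    n_overflow)`` when ``by_hour``.
    """
    counts = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
    hourly = np.zeros((grid.n_rows, grid.n_cols, 24), dtype=int) if by_hour else None
    n_skipped = 0
    n_overflow = 0
    from zoneinfo import ZoneInfo

    for ev in events:
        if not (np.isfinite(ev.x) and np.isfinite(ev.y)):
            n_skipped += 1
            continue
        col, row = grid.cell_index(ev.x, ev.y)
        if not grid.inside(col, row):
            n_overflow += 1
            continue
        counts[row, col] += 1
        if by_hour:
            hour = (
                pd.Timestamp(ev.clock_time, unit="s", tz="UTC")
                .tz_convert(ZoneInfo(tz))
                .hour
            )
            hourly[row, col, hour] += 1
    if n_skipped:
        logger.warning("%d events without a location were skipped", n_skipped)
    if by_hour:
        return counts, hourly, n_overflow
    return counts, n_overflow


def distance_to_resource(grid: Grid, resources: pd.DataFrame) -> np.ndarray:
    """Euclidean distance from each cell center to the nearest resource point."""
    if resources is None or len(resources) == 0:
        raise ConfigError("resource map must be non-empty")
    centers = grid.centers().reshape(-1, 2)
    pts = resources[["x", "y"]].to_numpy(dtype=float)
    d = cdist(centers, pts).min(axis=1)
    return d.reshape(grid.n_rows, grid.n_cols)


def normalized_rate(
    event_count: np.ndarray, occupancy_counts: np.ndarray, min_occupancy: int = 50
) -> np.ndarray:
    """Events per animal-time-step, defined only where occupancy is at least
    ``min_occupancy`` (NaN elsewhere)."""
    event_count = np.asarray(event_count, dtype=float)
    occ = np.asarray(occupancy_counts, dtype=float)
    out = np.full(event_count.shape, np.nan)
    ok = occ >= min_occupancy
    out[ok] = event_count[ok] / occ[ok]
    return out


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p-value over paired non-missing values."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise DataError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise DataError("need at least 3 paired non-missing values")
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        raise DataError("correlation undefined: zero variance")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)


def cell_hour_table(
    traj: TrajectorySet,
    events: EventList,
    grid: Grid,
    resources: pd.DataFrame,
    tz: str = "UTC",
    min_occupancy: int = 50,
) -> pd.DataFrame:
    """Assemble the cell-by-hour model table from pipeline outputs.

    One row per (used cell, hour of day): pooled event count, distance from
    the cell center to the nearest resource, hourly activity (mean
    displacement per interval across animals and days for that hour of day),
    total cell occupancy and the occupancy-normalized count. Cells below
    ``min_occupancy`` total occupancy are dropped.
    """
    occ, _ = occupancy(traj, grid)
    counts, hourly, _ = event_cell_counts(events, grid, by_hour=True, tz=tz)
    dist = distance_to_resource(grid, resources)

    disp = step_displacements(traj)
    hours = np.asarray(local_clock(traj.t0, traj.dt, traj.n_steps, tz).hour)
    hour_activity = np.full(24, np.nan)
    for h in range(24):
        vals = disp[:, hours == h]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            hour_activity[h] = vals.mean()

    rows = []
    used = np.argwhere(occ >= min_occupancy)
    for row, col in used:
        cell_id = int(row * grid.n_cols + col)
        for h in range(24):
            n_events = int(hourly[row, col, h])
            rows.append(
                {
                    "cell": cell_id,
                    "hour": h,
                    "event_count": n_events,
                    "distance": float(dist[row, col]),
                    "activity": float(hour_activity[h]),
                    "occupancy": int(occ[row, col]),
                    "normalized_count": n_events / float(occ[row, col]),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class MixedModelResult:
    """Fixed effects with Wald chi-square tests and variance components of the
    cell-hour linear mixed model."""

    params: pd.Series
    bse: pd.Series
    wald_chi2: pd.Series
    p_values: pd.Series
    group_var: float
    resid_var: float
    converged: bool
    used_random_effect: bool
    n_obs: int
    n_groups: int
    response: str

    def summary(self) -> str:
        lines = [
            f"Linear mixed model: {self.response} ~ distance + activity "
            "+ distance:activity + (1 | cell)",
            f"n_obs = {self.n_obs}, n_cells = {self.n_groups}, "
            f"REML = {self.used_random_effect}, converged = {self.converged}",
            "",
            f"{'effect':<22}{'estimate':>12}{'chi2':>12}{'p':>12}",
        ]
        for name in self.wald_chi2.index:
            lines.append(
                f"{name:<22}{self.params[name]:>12.4f}"
                f"{self.wald_chi2[name]:>12.3f}{self.p_values[name]:>12.4g}"
            )
        lines.append("")
        lines.append(f"{'cell intercept variance':<30}{self.group_var:>12.4f}")
        lines.append(f"{'residual variance':<30}{self.resid_var:>12.4f}")
        return "\n".join(lines)


_FIXED_EFFECTS = ["distance", "activity", "distance:activity"]


def fit_cell_hour_model(table: pd.DataFrame, response: str = "raw") -> MixedModelResult:
    """Fit events ~ distance + activity + distance x activity + (1 | cell).

    ``response`` selects the raw per-cell-hour event count
    (``event_count`` column) or the occupancy-normalized count
    (``normalized_count``). Predictors are z-scaled (mean 0, sd 1) before
    fitting. The model is REML with a random intercept per cell; each fixed
    effect gets a 1-df Wald chi-square test. A singular or non-converging
    random-effect fit is flagged and refit as fixed-effects-only OLS.
    """
    col = {"raw": "event_count", "normalized": "normalized_count"}.get(response)
    if col is None:
        raise ConfigError("response must be 'raw' or 'normalized'")
    for needed in ("cell", col, "distance", "activity"):
        if needed not in table.columns:
            raise DataError(f"model table lacks column {needed!r}")
    if table["cell"].nunique() < 2:
        raise DataError("need at least 2 grid cells to fit the mixed model")

    df = table[["cell", "distance", "activity"]].copy()
    for pred in ("distance", "activity"):
        v = df[pred].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if sd == 0:
            raise DataError(f"predictor {pred!r} has zero variance")
        df[pred] = (v - v.mean()) / sd
    df["y"] = table[col].to_numpy(dtype=float)

    used_random_effect = True
    converged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("y ~ distance + activity + distance:activity",
                                data=df, groups=df["cell"])
            fit = model.fit(reml=True)
        converged = bool(fit.converged)
        group_var = float(fit.cov_re.iloc[0, 0])
        resid_var = float(fit.scale)
        params = fit.params
        bse = fit.bse
        if not converged:
            raise RuntimeError("mixed model did not converge")
    except Exception as exc:  # singular fit or optimizer failure
        logger.warning("random-intercept fit failed (%s); falling back to OLS", exc)
        used_random_effect = False
        fit = smf.ols("y ~ distance + activity + distance:activity", data=df).fit()
        converged = True
        group_var = 0.0
        resid_var = float(fit.mse_resid)
        params = fit.params
        bse = fit.bse

    wald = pd.Series(
        {name: (params[name] / bse[name]) ** 2 for name in _FIXED_EFFECTS}
    )
    pvals = pd.Series({name: float(stats.chi2.sf(wald[name], df=1)) for name in _FIXED_EFFECTS})
    return MixedModelResult(
        params=params[["Intercept"] + _FIXED_EFFECTS],
        bse=bse[["Intercept"] + _FIXED_EFFECTS],
        wald_chi2=wald,
        p_values=pvals,
        group_var=group_var,
        resid_var=resid_var,
        converged=converged,
        used_random_effect=used_random_effect,
        n_obs=len(df),
        n_groups=int(df["cell"].nunique()),
        response=response,
    )
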