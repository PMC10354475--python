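"""CSV readers and writers for fixes, resources, boundaries, trajectories,
group timelines and event tables.

All files are UTF-8, comma-separated, header required. Coordinates must be
supplied in a projected metric system (metres east / metres north): every
radius and speed in the pipeline is metric. Timestamps are accepted either
as epoch seconds or as ISO-8601 strings and are stored internally as epoch
seconds UTC.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import ConfigError, FormatError
from .events import Event, EventList
from .grouping import GroupTimeline
from .trajectories import TrajectorySet

logger = logging.getLogger("fisfus")

__all__ = [
    "read_fixes",
    "write_fixes",
    "read_resources",
    "write_resources",
    "read_boundary",
    "read_trajectories",
    "write_trajectories",
    "read_timeline",
    "write_timeline",
    "read_events",
    "write_events",
    "DEFAULT_DIALECT",
    "RESOURCE_LABELS",
]

#: Logical field -> column name used when no dialect mapping is given.
DEFAULT_DIALECT: dict[str, str] = {
    "id": "id",
    "time": "time",
    "x": "x",
    "y": "y",
    "nsat": "nsat",
}

RESOURCE_LABELS = frozenset({"food", "water"})


def _parse_times(col: pd.Series) -> np.ndarray:
    """Parse a time column to epoch seconds UTC (floats).

    Numeric values are taken as epoch seconds; anything else must be
    ISO-8601. A row that parses to neither raises a row-level FormatError.
    """
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().all():
        return numeric.to_numpy(dtype=float)
    parsed = pd.to_datetime(col, errors="coerce", utc=True, format="ISO8601")
    bad = parsed.isna() & col.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(f"unparsable timestamp {col.iloc[row]!r} at data row {row}")
    if parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise FormatError(f"missing timestamp at data row {row}")
    return parsed.astype("int64").to_numpy() / 1e9


def read_fixes(path, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a raw GPS fix table.

    Parameters
    ----------
    path
        CSV file with columns for individual id, time, x and y (metres),
        plus an optional satellite count.
    dialect
        Mapping from the logical names ``id``, ``time``, ``x``, ``y``,
        ``nsat`` to the column names actually present. Unmapped fields fall
        back to their logical name.

    Returns
    -------
    pandas.DataFrame
        Columns ``id`` (str), ``time`` (epoch seconds UTC), ``x``, ``y``
        (metres) and ``nsat`` (float, NaN when absent), sorted by
        ``(id, time)``. Duplicate (id, time) rows are collapsed to their
        first occurrence with a logged warning.
    """
    names = dict(DEFAULT_DIALECT)
    if dialect:
        names.update(dialect)
    raw = pd.read_csv(path, float_precision="round_trip")
    for field in ("id", "time", "x", "y"):
        if names[field] not in raw.columns:
            raise FormatError(f"missing required column {names[field]!r} (field {field!r})")
    out = pd.DataFrame(
        {
            "id": raw[names["id"]].astype(str),
            "time": _parse_times(raw[names["time"]]),
            "x": pd.to_numeric(raw[names["x"]]),
            "y": pd.to_numeric(raw[names["y"]]),
        }
    )
    if names["nsat"] in raw.columns:
        out["nsat"] = pd.to_numeric(raw[names["nsat"]])
        if (out["nsat"].dropna() < 0).any():
            raise FormatError("negative satellite count")
    else:
        out["nsat"] = np.nan
    if not np.isfinite(out["time"]).all():
        raise FormatError("non-finite timestamp")
    if not (np.isfinite(out["x"]) & np.isfinite(out["y"])).all():
        raise FormatError("non-finite coordinate")
    out = out.sort_values(["id", "time"], kind="mergesort").reset_index(drop=True)
    dup = out.duplicated(["id", "time"])
    if dup.any():
        logger.warning("collapsed %d duplicate (id, time) fixes", int(dup.sum()))
        out = out[~dup].reset_index(drop=True)
    return out


def write_fixes(fixes: pd.DataFrame, path) -> None:
    """Write a fix table in the `id,time,x,y[,nsat]` dialect."""
    cols = ["id", "time", "x", "y"]
    if "nsat" in fixes.columns and fixes["nsat"].notna().any():
        cols.append("nsat")
    fixes.to_csv(path, columns=cols, index=False)


def read_resources(path) -> pd.DataFrame:
    """Read a resource map (`label,x,y`; labels drawn from {food, water})."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("label", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    bad = set(df["label"].astype(str)) - RESOURCE_LABELS
    if bad:
        raise FormatError(f"unknown resource labels {sorted(bad)}; expected food/water")
    if df.empty:
        raise FormatError("resource map is empty")
    return pd.DataFrame(
        {
            "label": df["label"].astype(str),
            "x": pd.to_numeric(df["x"]),
            "y": pd.to_numeric(df["y"]),
        }
    )


def write_resources(resources: pd.DataFrame, path) -> None:
    resources.to_csv(path, columns=["label", "x", "y"], index=False)


def read_boundary(path) -> Polygon:
    """Read a paddock boundary polygon from an `x,y` vertex list."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("x", "y"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    if len(df) < 3:
        raise FormatError("boundary polygon needs at least 3 vertices")
    poly = Polygon(zip(df["x"].astype(float), df["y"].astype(float)))
    if not poly.is_valid:
        raise FormatError("boundary polygon is self-intersecting")
    if poly.area <= 0:
        raise ConfigError("boundary polygon has zero area")
    return poly


# -- trajectories ---------------------------------------------------------

def write_trajectories(traj: TrajectorySet, path) -> None:
    """Write a TrajectorySet as `id,step,time,x,y` rows (present cells only)."""
    traj.to_fixes().to_csv(path, columns=["id", "step", "time", "x", "y"], index=False)


def read_trajectories(path, dt: float | None = None) -> TrajectorySet:
    """Read a TrajectorySet written by :func:`write_trajectories`.

    ``dt`` is inferred from the step/time columns when at least two distinct
    steps are present; otherwise it must be supplied.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("id", "step", "time", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    if df.empty:
        raise FormatError("empty trajectory file")
    df["id"] = df["id"].astype(str)
    steps = df["step"].to_numpy(dtype=int)
    times = df["time"].to_numpy(dtype=float)
    if dt is None:
        order = np.argsort(steps)
        s, t = steps[order], times[order]
        distinct = s != s[0]
        if not distinct.any():
            raise FormatError("cannot infer dt from a single step; pass dt explicitly")
        k = int(np.flatnonzero(distinct)[0])
        dt = (t[k] - t[0]) / (s[k] - s[0])
    t0 = float(times[0] - steps[0] * dt)
    ids = sorted(df["id"].unique())
    index = {i: k for k, i in enumerate(ids)}
    n_steps = int(steps.max()) + 1
    xy = np.full((len(ids), n_steps, 2), np.nan)
    rows = df["id"].map(index).to_numpy()
    xy[rows, steps, 0] = df["x"].to_numpy(dtype=float)
    xy[rows, steps, 1] = df["y"].to_numpy(dtype=float)
    return TrajectorySet(ids, t0, float(dt), xy)


# -- group timelines ------------------------------------------------------

def write_timeline(timeline: GroupTimeline, path) -> None:
    """Write a GroupTimeline as `step,individual,group_label` rows.

    Only present individuals appear; unassigned components (min group size
    above 1) carry the label ``unassigned``.
    """
    step_idx, ind_idx = np.nonzero(timeline.labels >= -2)
    mask = timeline.labels[step_idx, ind_idx] != -1
    step_idx, ind_idx = step_idx[mask], ind_idx[mask]
    labels = timeline.labels[step_idx, ind_idx]
    pd.DataFrame(
        {
            "step": step_idx,
            "individual": [timeline.ids[i] for i in ind_idx],
            "group_label": np.where(labels < 0, "unassigned", labels.astype(str)),
        }
    ).to_csv(path, index=False)


def read_timeline(path, n_steps: int | None = None, t0: float = 0.0, dt: float = 6.0) -> GroupTimeline:
    """Read a GroupTimeline written by :func:`write_timeline`."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("step", "individual", "group_label"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    df["individual"] = df["individual"].astype(str)
    ids = sorted(df["individual"].unique())
    index = {i: k for k, i in enumerate(ids)}
    steps = df["step"].to_numpy(dtype=int)
    if n_steps is None:
        n_steps = int(steps.max()) + 1 if len(steps) else 0
    labels = np.full((n_steps, len(ids)), -1, dtype=int)
    raw = df["group_label"].astype(str).to_numpy()
    vals = np.where(raw == "unassigned", "-2", raw).astype(int)
    labels[steps, df["individual"].map(index).to_numpy()] = vals
    return GroupTimeline(ids, labels, t0, dt)


# -- events ---------------------------------------------------------------

def _join_members(groups: Iterable[frozenset]) -> str:
    return "|".join(";".join(sorted(g)) for g in groups)


def _split_members(text: str) -> tuple[frozenset, ...]:
    if not isinstance(text, str) or text == "":
        return ()
    return tuple(frozenset(part.split(";")) for part in text.split("|"))


def write_events(events: EventList, path) -> None:
    """Write an EventList as CSV.

    Columns: ``kind, step, clock_time, x, y, parent_members, child_members``.
    ``parent_members`` are the group(s) at the earlier step and
    ``child_members`` the group(s) at the later step, so a fission has one
    parent set and several child sets, a fusion the reverse. Member sets are
    ``;``-joined sorted ids; multiple sets are ``|``-separated. The file
    round-trips losslessly through :func:`read_events`.
    """
    rows = []
    for ev in events:
        if ev.kind == "fission":
            parents, children = (ev.reference,), ev.branches
        else:
            parents, children = ev.branches, (ev.reference,)
        rows.append(
            {
                "kind": ev.kind,
                "step": int(ev.step),
                "clock_time": repr(float(ev.clock_time)),
                "x": "" if np.isnan(ev.x) else repr(float(ev.x)),
                "y": "" if np.isnan(ev.y) else repr(float(ev.y)),
                "parent_members": _join_members(parents),
                "child_members": _join_members(children),
            }
        )
    cols = ["kind", "step", "clock_time", "x", "y", "parent_members", "child_members"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_events(path) -> EventList:
    """Read an event table written by :func:`write_events`."""
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    for col in ("kind", "step", "clock_time", "x", "y", "parent_members", "child_members"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    events = []
    for row in df.itertuples(index=False):
        kind = str(row.kind)
        if kind not in ("fission", "fusion"):
            raise FormatError(f"unknown event kind {kind!r}")
        parents = _split_members(row.parent_members)
        children = _split_members(row.child_members)
        if kind == "fission":
            reference, branches = parents[0], children
        else:
            reference, branches = children[0], parents
        events.append(
            Event(
                kind=kind,
                step=int(row.step),
                clock_time=float(row.clock_time),
                x=float(row.x) if str(row.x) != "" else float("nan"),
                y=float(row.y) if str(row.y) != "" else float("nan"),
                reference=reference,
                branches=branches,
            )
        )
    return EventList(events)
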