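"""Synthetic herds with scripted group structure and known fission-fusion
ground truth, plus small constructed fixtures for the grouping semantics.

The herd generator is a test harness, not a behavioural model: individuals
track their scheduled group's centroid (piecewise-linear between waypoints)
with temporally autocorrelated within-group dispersion (AR(1), so paths are
smooth) plus white GPS noise, and optional i.i.d. missing fixes. Scheduled
splits and merges are the ground truth against which detected events are
checked, inside a tolerance window derived from the centroid geometry
(backdating joins to outer-radius crossings makes detected event times
noise-sensitive by construction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ScriptError
from .trajectories import TrajectorySet

__all__ = [
    "HerdScript",
    "TruthEvent",
    "GroundTruth",
    "simulate_herd",
    "split_merge_script",
    "detection_windows",
    "fig1_fixture",
    "jitter_fixture",
    "synthetic_cell_hour_table",
    "synthetic_occupancy_table",
]


@dataclass(frozen=True)
class TruthEvent:
    kind: str  # fission | fusion
    step: int  # schedule breakpoint at which the partition changes
    reference: frozenset  # the larger (parent / merged) member index set
    branches: tuple[frozenset, ...]


@dataclass(frozen=True)
class GroundTruth:
    events: tuple[TruthEvent, ...]

    def counts(self) -> dict[str, int]:
        out = {"fission": 0, "fusion": 0}
        for ev in self.events:
            out[ev.kind] += 1
        return out


@dataclass(frozen=True)
class HerdScript:
    """Scripted group-structured movement.

    ``schedule`` lists (step, partition) pairs: the partition (a tuple of
    tuples of individual indices) applies from that step until the next
    breakpoint; consecutive partitions must differ by exactly one split or
    one merge. ``waypoints`` maps (segment index, group index within that
    segment's partition) to a list of (step, x, y) waypoints spanning the
    segment; group centroids interpolate linearly between them.

    Dispersion and noise defaults emulate a grazing herd tracked at 6 s:
    within-group spread well below the 30 m inner radius, metre-scale GPS
    jitter, and a few percent missing fixes.
    """

    n_individuals: int
    n_steps: int
    schedule: tuple
    waypoints: dict
    dt: float = 6.0
    t0: float = 0.0
    spread: float = 5.0
    ar_phi: float = 0.9
    gps_noise_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0
    max_centroid_speed: float = 2.0
    min_separation: float = 100.0

    def segments(self) -> list[tuple[int, int, tuple]]:
        """(start_step, end_step_exclusive, partition) per schedule segment."""
        out = []
        for k, (step, part) in enumerate(self.schedule):
            end = self.schedule[k + 1][0] if k + 1 < len(self.schedule) else self.n_steps
            out.append((step, end, part))
        return out

    def validate(self) -> None:
        if not self.schedule or self.schedule[0][0] != 0:
            raise ScriptError("schedule must start at step 0")
        steps = [s for s, _ in self.schedule]
        if steps != sorted(set(steps)):
            raise ScriptError("schedule steps must be strictly increasing")
        if steps[-1] >= self.n_steps:
            raise ScriptError("schedule breakpoint beyond the simulation")
        universe = frozenset(range(self.n_individuals))
        for _, part in self.schedule:
            flat = [i for g in part for i in g]
            if len(flat) != len(set(flat)) or frozenset(flat) != universe:
                raise ScriptError("each scheduled partition must cover all individuals")
        for (_, a), (_, b) in zip(self.schedule, self.schedule[1:]):
            _schedule_diff(a, b)  # raises unless one split or one merge
        for seg_idx, (start, end, part) in enumerate(self.segments()):
            for gi in range(len(part)):
                wps = self.waypoints.get((seg_idx, gi))
                if not wps:
                    raise ScriptError(f"missing waypoints for segment {seg_idx}, group {gi}")
                wsteps = [w[0] for w in wps]
                if wsteps != sorted(wsteps) or wsteps[0] != start or wsteps[-1] < end - 1:
                    raise ScriptError(
                        f"waypoints for segment {seg_idx}, group {gi} must span the segment"
                    )
                for (s0, x0, y0), (s1, x1, y1) in zip(wps, wps[1:]):
                    if s1 > s0:
                        speed = math.hypot(x1 - x0, y1 - y0) / ((s1 - s0) * self.dt)
                        if speed > self.max_centroid_speed + 1e-9:
                            raise ScriptError("centroid speed exceeds max_centroid_speed")
        self._check_separation()

    def _check_separation(self) -> None:
        """Distinct scheduled groups must actually separate: every group pair
        in a multi-group segment must reach ``min_separation`` at some step.
        (Centroids are necessarily close during the ramps adjacent to the
        split/merge breakpoints themselves.)"""
        for seg_idx, (start, end, part) in enumerate(self.segments()):
            if len(part) < 2:
                continue
            tracks = [
                _interp_track(self.waypoints[(seg_idx, gi)], start, end)
                for gi in range(len(part))
            ]
            for a in range(len(part)):
                for b in range(a + 1, len(part)):
                    d = np.hypot(*(tracks[a] - tracks[b]).T)
                    if d.max() < self.min_separation:
                        raise ScriptError(
                            "scheduled groups never reach min_separation; "
                            "events would not be geometrically resolvable"
                        )


def _schedule_diff(prev: tuple, cur: tuple):
    """Classify two consecutive partitions as one split or one merge."""
    a = {frozenset(g) for g in prev}
    b = {frozenset(g) for g in cur}
    gone = a - b
    new = b - a
    if len(gone) == 1 and len(new) >= 2:
        (parent,) = gone
        if frozenset().union(*new) == parent:
            return ("fission", parent, tuple(sorted(new, key=sorted)))
    if len(new) == 1 and len(gone) >= 2:
        (merged,) = new
        if frozenset().union(*gone) == merged:
            return ("fusion", merged, tuple(sorted(gone, key=sorted)))
    raise ScriptError("consecutive scheduled partitions must differ by one split or one merge")


def _interp_track(waypoints, start: int, end: int) -> np.ndarray:
    """Centroid positions for steps [start, end) from (step, x, y) waypoints."""
    steps = np.arange(start, end)
    ws = np.array([w[0] for w in waypoints], dtype=float)
    wx = np.array([w[1] for w in waypoints], dtype=float)
    wy = np.array([w[2] for w in waypoints], dtype=float)
    return np.column_stack([np.interp(steps, ws, wx), np.interp(steps, ws, wy)])


def _group_centroid_per_individual(script: HerdScript) -> np.ndarray:
    """(n_individuals, n_steps, 2) array of each individual's group centroid."""
    out = np.empty((script.n_individuals, script.n_steps, 2))
    for seg_idx, (start, end, part) in enumerate(script.segments()):
        for gi, group in enumerate(part):
            track = _interp_track(script.waypoints[(seg_idx, gi)], start, end)
            for i in group:
                out[i, start:end, :] = track
    return out


def _ar1(rng: np.random.Generator, shape: tuple, n_steps: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) series along the last axis, marginal sd ``sd``."""
    out = np.empty(shape + (n_steps,))
    if sd == 0:
        out[...] = 0.0
        return out
    eps_sd = sd * math.sqrt(1.0 - phi * phi)
    out[..., 0] = rng.normal(0.0, sd, shape)
    for k in range(1, n_steps):
        out[..., k] = phi * out[..., k - 1] + rng.normal(0.0, eps_sd, shape)
    return out


def _ground_truth(script: HerdScript) -> GroundTruth:
    events = []
    for (_, prev), (step, cur) in zip(script.schedule, script.schedule[1:]):
        kind, reference, branches = _schedule_diff(prev, cur)
        events.append(TruthEvent(kind=kind, step=step, reference=reference, branches=branches))
    return GroundTruth(events=tuple(events))


def simulate_herd(script: HerdScript) -> tuple[TrajectorySet, GroundTruth]:
    """Simulate a scripted herd; identical seed gives identical output.

    Individuals follow their scheduled group centroid plus an isotropic
    AR(1) within-group displacement (marginal sd ``spread``) plus white GPS
    noise; fixes go missing i.i.d. at ``missing_rate``.
    """
    script.validate()
    rng = np.random.default_rng(script.seed)
    n, n_steps = script.n_individuals, script.n_steps
    centroids = _group_centroid_per_individual(script)
    offsets = _ar1(rng, (n, 2), n_steps, script.spread, script.ar_phi)
    xy = centroids + np.moveaxis(offsets, 1, 2)
    if script.gps_noise_sd > 0:
        xy = xy + rng.normal(0.0, script.gps_noise_sd, (n, n_steps, 2))
    if script.missing_rate > 0:
        missing = rng.random((n, n_steps)) < script.missing_rate
        xy[missing] = np.nan
    ids = [f"s{i:03d}" for i in range(n)]
    return TrajectorySet(ids, script.t0, script.dt, xy), _ground_truth(script)


def split_merge_script(
    n_individuals: int = 50,
    n_steps: int = 5000,
    n_cycles: int = 10,
    dt: float = 6.0,
    home: tuple = (1000.0, 1000.0),
    sep_distance: float = 200.0,
    sep_speed: float = 1.0,
    split_frac: float = 0.2,
    merge_frac: float = 0.7,
    spread: float = 5.0,
    gps_noise_sd: float = 1.0,
    missing_rate: float = 0.03,
    seed: int = 0,
) -> HerdScript:
    """Script of ``n_cycles`` split/merge cycles of a two-way herd split.

    Each cycle of length ``n_steps // n_cycles`` splits the herd into two
    fixed halves at ``split_frac`` of the cycle; the second half's centroid
    walks out ``sep_distance`` metres at ``sep_speed``, holds, walks back,
    and the halves re-merge at ``merge_frac`` of the cycle. Defaults emulate
    the tracked herd (50 animals, 6 s fixes, ~3% missing fixes, 5 m
    within-group spread, 1 m GPS noise).
    """
    cycle = n_steps // n_cycles
    split_off = int(cycle * split_frac)
    merge_off = int(cycle * merge_frac)
    ramp = int(math.ceil(sep_distance / (sep_speed * dt)))
    if not (0 < split_off and split_off + ramp < merge_off - ramp and merge_off < cycle):
        raise ScriptError("cycle too short for the requested excursion geometry")
    half = n_individuals // 2
    group_a = tuple(range(half))
    group_b = tuple(range(half, n_individuals))
    whole = tuple(range(n_individuals))
    hx, hy = home

    schedule: list = [(0, (whole,))]
    waypoints: dict = {}
    seg = 0
    waypoints[(seg, 0)] = [(0, hx, hy), (split_off, hx, hy)]
    for k in range(n_cycles):
        split_at = k * cycle + split_off
        merge_at = k * cycle + merge_off
        next_split = (k + 1) * cycle + split_off if k + 1 < n_cycles else n_steps - 1
        schedule.append((split_at, (group_a, group_b)))
        seg += 1
        waypoints[(seg, 0)] = [(split_at, hx, hy), (merge_at, hx, hy)]
        waypoints[(seg, 1)] = [
            (split_at, hx, hy),
            (split_at + ramp, hx + sep_distance, hy),
            (merge_at - ramp, hx + sep_distance, hy),
            (merge_at, hx, hy),
        ]
        schedule.append((merge_at, (whole,)))
        seg += 1
        waypoints[(seg, 0)] = [(merge_at, hx, hy), (max(next_split, merge_at + 1), hx, hy)]
    return HerdScript(
        n_individuals=n_individuals,
        n_steps=n_steps,
        schedule=tuple(schedule),
        waypoints=waypoints,
        dt=dt,
        spread=spread,
        gps_noise_sd=gps_noise_sd,
        missing_rate=missing_rate,
        seed=seed,
    )


def detection_windows(
    script: HerdScript,
    truth: GroundTruth,
    r_out: float = 50.0,
    margin_m: float | None = None,
) -> list[tuple[int, int]]:
    """Step window within which each scripted event should be detected.

    Detected fission/fusion times are anchored at outer-radius crossings of
    the *dyadic* distances, which straddle the crossing of the inter-centroid
    distance by up to the combined within-group offsets and noise. The window
    is the centroid-distance crossing of ``r_out`` widened by
    ``margin_m`` metres of separation converted to steps via the local
    separation speed, plus 2 steps. The default margin is
    ``8 * (spread + gps_noise_sd)`` (two individuals at ~4 sd each).
    """
    if margin_m is None:
        margin_m = 8.0 * (script.spread + script.gps_noise_sd)
    segments = script.segments()
    windows = []
    for ev in truth.events:
        if len(ev.branches) != 2:
            raise ScriptError("detection windows are defined for two-way events only")
        if ev.kind == "fission":
            seg_idx = next(i for i, (s, _, _) in enumerate(segments) if s == ev.step)
        else:
            seg_idx = next(i for i, (_, e, _) in enumerate(segments) if e == ev.step)
        start, end, part = segments[seg_idx]
        gi = [part.index(tuple(sorted(b))) for b in ev.branches]
        tracks = [_interp_track(script.waypoints[(seg_idx, g)], start, end) for g in gi]
        d = np.hypot(*(tracks[0] - tracks[1]).T)
        above = d > r_out
        if ev.kind == "fission":
            k = int(np.argmax(above))  # first step beyond r_out
        else:
            k = d.size - 1 - int(np.argmax(above[::-1]))  # last step beyond r_out
        slope = abs(d[min(k + 1, d.size - 1)] - d[max(k - 1, 0)]) / 2.0
        slope = max(slope, 1e-9)
        tol = int(math.ceil(margin_m / slope)) + 2
        cross = start + k
        windows.append((cross - tol, cross + tol))
    return windows


# ---------------------------------------------------------------------------
# constructed fixtures
# ---------------------------------------------------------------------------

def fig1_fixture(n_steps: int = 60, dt: float = 6.0) -> TrajectorySet:
    """Five noiseless trajectories exercising the double-radius semantics.

    A stationary individual S sits at the origin; four others move radially
    (distances in metres, one step = ``dt`` seconds):

    - A approaches from 80 m to 12 m (2 m per step): joins, with the join
      backdated to its outer-radius crossing (step 16 for the 30/50 radii).
    - B starts at 12 m and departs to 80 m: leaves at its outer-radius
      crossing (step 29).
    - C approaches only to 36 m and retreats: never inside the inner
      radius, so never grouped.
    - D oscillates between 20 m and 45 m: crosses the inner but never the
      outer radius, so it remains grouped throughout.
    """
    k = np.arange(n_steps, dtype=float)
    xy = np.zeros((5, n_steps, 2))
    # S stays at the origin
    xy[1, :, 0] = np.maximum(80.0 - 2.0 * k, 12.0)  # A, east
    b = np.where(k < 10, 12.0, 12.0 + 2.0 * (k - 10))
    xy[2, :, 0] = -np.minimum(b, 80.0)  # B, west
    c = np.maximum(80.0 - 2.0 * k, 36.0)
    c = np.where(k > 22, np.minimum(36.0 + 2.0 * (k - 22), 80.0), c)
    xy[3, :, 1] = c  # C, north
    xy[4, :, 1] = -(32.5 + 12.5 * np.cos(2 * np.pi * k / 20.0))  # D, south
    return TrajectorySet(["S", "A", "B", "C", "D"], 0.0, dt, xy)


def jitter_fixture(
    seed: int = 0,
    n_per_group: int = 5,
    n_steps: int = 600,
    cycle: int = 150,
    base: float = 31.0,
    peak: float = 58.0,
    rise: int = 25,
    hold: int = 15,
    spread: float = 2.0,
    ar_phi: float = 0.9,
    gps_noise_sd: float = 0.5,
    dt: float = 6.0,
) -> TrajectorySet:
    """Two subgroups whose separation oscillates across the 30-50 m band.

    The inter-centroid distance hovers just above the 30 m inner radius
    (where single-radius 30 m grouping flickers with individual jitter),
    excurses past the 50 m outer radius once per cycle (so sticky grouping
    registers one clean split and one clean merge), and returns. Designed so
    that membership under sticky(30, 50) is far more stable than per-step
    single-radius grouping of the same data.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_steps)
    ph = t % cycle
    hover = cycle - 2 * rise - hold
    d = np.full(n_steps, base)
    up = (ph >= hover) & (ph < hover + rise)
    d[up] = base + (peak - base) * (ph[up] - hover) / rise
    top = (ph >= hover + rise) & (ph < hover + rise + hold)
    d[top] = peak
    down = (ph >= hover + rise + hold) & (ph < hover + 2 * rise + hold)
    d[down] = peak - (peak - base) * (ph[down] - hover - rise - hold) / rise

    n = 2 * n_per_group
    centroids = np.zeros((n, n_steps, 2))
    centroids[n_per_group:, :, 0] = d[None, :]
    offsets = _ar1(rng, (n, 2), n_steps, spread, ar_phi)
    xy = centroids + np.moveaxis(offsets, 1, 2)
    xy += rng.normal(0.0, gps_noise_sd, xy.shape)
    ids = [f"a{i}" for i in range(n_per_group)] + [f"b{i}" for i in range(n_per_group)]
    return TrajectorySet(ids, 0.0, dt, xy)


# ---------------------------------------------------------------------------
# synthetic model tables
# ---------------------------------------------------------------------------

def synthetic_cell_hour_table(
    n_cells: int = 200,
    n_hours: int = 24,
    intercept: float = 1.0,
    beta_distance: float = -0.5,
    beta_activity: float = 0.3,
    beta_interaction: float = 0.0,
    cell_sd: float = 0.2,
    resid_sd: float = 1.0,
    seed: int = 0,
):
    """Cell-by-hour table with known coefficients for parameter recovery.

    Distance is one draw per cell, activity follows a smooth diel pattern;
    both are generated standardized so the fitted (z-scaled) coefficients
    are directly comparable to the generating betas. The response adds a
    Gaussian cell intercept (sd ``cell_sd``) and residual noise.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    dist = rng.normal(0.0, 1.0, n_cells)
    hours = np.arange(n_hours)
    act = np.sin(2 * np.pi * (hours - 6) / n_hours)
    act = (act - act.mean()) / act.std()
    u = rng.normal(0.0, cell_sd, n_cells)

    cell_idx = np.repeat(np.arange(n_cells), n_hours)
    hour_idx = np.tile(hours, n_cells)
    dz = dist[cell_idx]
    az = act[hour_idx]
    y = (
        intercept
        + beta_distance * dz
        + beta_activity * az
        + beta_interaction * dz * az
        + u[cell_idx]
        + rng.normal(0.0, resid_sd, n_cells * n_hours)
    )
    return pd.DataFrame(
        {
            "cell": cell_idx,
            "hour": hour_idx,
            "event_count": y,
            "normalized_count": y,
            "distance": dz,
            "activity": az,
        }
    )


def synthetic_occupancy_table(
    n_cells: int = 500,
    max_distance: float = 1000.0,
    base_occupancy: float = 5000.0,
    decay: float = 400.0,
    occupancy_noise_sd: float = 0.5,
    events_per_step: float = 0.01,
    seed: int = 0,
):
    """Per-cell occupancy and event counts with events uniform per unit of use.

    Occupancy concentrates near resources (exponential decay in resource
    distance with lognormal scatter) while events are Poisson with a
    constant per-animal-time-step rate, so raw counts inherit the occupancy
    gradient but the occupancy-normalized rate carries no distance signal.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    distance = rng.uniform(0.0, max_distance, n_cells)
    occ = np.rint(
        base_occupancy
        * np.exp(-distance / decay)
        * np.exp(rng.normal(0.0, occupancy_noise_sd, n_cells))
    ).astype(int)
    occ = np.maximum(occ, 1)
    events = rng.poisson(events_per_step * occ)
    return pd.DataFrame({"distance": distance, "occupancy": occ, "event_count": events})
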