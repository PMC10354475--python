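"""Temporal group graph and fission/fusion event extraction.

Groups at consecutive steps are linked into a directed graph: one node per
(step, group), and an edge from a group at step ``t`` to a group at step
``t + 1`` whenever their member sets share an individual that is present at
both steps. A node with two or more outgoing edges marks a fission, dated at
that node's step (the last step the larger group still existed); a node with
two or more incoming edges marks a fusion, dated at that node's step (the
step the merged group formed). A node may yield both.

Individuals missing at either step are ignored when computing overlap, so
data dropout ("disappearances" and "reappearances") never produces events:
a returning individual re-enters the graph inside whatever group its sticky
together-intervals place it in.

Event counting is per node: a simultaneous three-way split is one fission
(its parts are available in ``branches`` for per-branch re-analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import networkx as nx
import numpy as np

from .grouping import GroupTimeline
from .trajectories import TrajectorySet

logger = logging.getLogger("fisfus")

__all__ = [
    "Event",
    "EventList",
    "GroupGraph",
    "build_group_graph",
    "extract_events",
    "locate_event",
    "detect_events",
]

_KIND_RANK = {"fusion": 0, "fission": 1}


@dataclass(frozen=True)
class Event:
    """One fission or fusion event.

    ``reference`` is the larger group (the pre-split group for a fission,
    the merged group for a fusion); ``branches`` are the resulting or
    contributing groups. ``x, y`` is the arithmetic mean of the positions of
    the reference group's members present at ``step`` (NaN when all are
    missing).
    """

    kind: str
    step: int
    clock_time: float
    x: float
    y: float
    reference: frozenset
    branches: tuple[frozenset, ...]

    def sort_key(self):
        return (self.step, _KIND_RANK[self.kind], tuple(sorted(self.reference)))


class EventList:
    """Deterministically ordered list of events.

    Sorted by (step, kind with fusion first, reference members); a node that
    is simultaneously a merge target and a split source therefore lists its
    fusion before its fission.
    """

    def __init__(self, events: Iterable[Event] = ()) -> None:
        self.events: tuple[Event, ...] = tuple(sorted(events, key=Event.sort_key))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventList):
            return NotImplemented
        if len(self) != len(other):
            return False
        for a, b in zip(self.events, other.events):
            same_loc = (a.x == b.x or (np.isnan(a.x) and np.isnan(b.x))) and (
                a.y == b.y or (np.isnan(a.y) and np.isnan(b.y))
            )
            if not (
                a.kind == b.kind
                and a.step == b.step
                and a.clock_time == b.clock_time
                and same_loc
                and a.reference == b.reference
                and set(a.branches) == set(b.branches)
            ):
                return False
        return True

    def counts(self) -> dict[str, int]:
        out = {"fission": 0, "fusion": 0}
        for ev in self.events:
            out[ev.kind] += 1
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        c = self.counts()
        return f"EventList(fissions={c['fission']}, fusions={c['fusion']})"


class GroupGraph:
    """Directed temporal graph of (step, group) nodes.

    Node keys are ``(step, label)``; node attributes carry ``members``
    (frozenset of ids present in the group at that step) and ``centroid``
    (mean position of those members, NaN pair if all are missing). Edges run
    only between consecutive steps and exist iff the member sets intersect
    when restricted to individuals present at both steps.
    """

    def __init__(self, graph: nx.DiGraph, t0: float, dt: float) -> None:
        self.graph = graph
        self.t0 = float(t0)
        self.dt = float(dt)

    def members(self, node) -> frozenset:
        return self.graph.nodes[node]["members"]

    def centroid(self, node) -> tuple[float, float]:
        return self.graph.nodes[node]["centroid"]

    def write_edgelist(self, path) -> None:
        """Dump the graph as a plain-text edge list for inspection."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("step,label,next_step,next_label\n")
            for (s, g), (s2, g2) in sorted(self.graph.edges()):
                fh.write(f"{s},{g},{s2},{g2}\n")


def build_group_graph(timeline: GroupTimeline, traj: TrajectorySet) -> GroupGraph:
    """Link per-step groups into the directed temporal graph."""
    if traj.n_steps != timeline.n_steps or traj.ids != timeline.ids:
        raise ValueError("timeline and trajectory must share steps and individuals")
    g = nx.DiGraph()
    for t in range(timeline.n_steps):
        groups = timeline.groups_at(t)
        for lab, idx in enumerate(groups):
            pts = traj.xy[idx, t, :]
            with np.errstate(invalid="ignore"):
                centroid = tuple(np.nanmean(pts, axis=0)) if np.isfinite(pts).any() else (
                    float("nan"),
                    float("nan"),
                )
            g.add_node(
                (t, lab),
                members=frozenset(timeline.ids[i] for i in idx),
                centroid=centroid,
            )
        if t > 0:
            prev_lab = timeline.labels[t - 1]
            cur_lab = timeline.labels[t]
            shared = (prev_lab >= 0) & (cur_lab >= 0)
            pairs = {
                (int(a), int(b))
                for a, b in zip(prev_lab[shared], cur_lab[shared])
            }
            for a, b in pairs:
                g.add_edge((t - 1, a), (t, b))
    return GroupGraph(g, timeline.t0, timeline.dt)


def extract_events(graph: GroupGraph) -> EventList:
    """Fission/fusion events from node degrees of the group graph.

    One fission per node with out-degree >= 2 and one fusion per node with
    in-degree >= 2, each dated and located at that node; the total event
    count is the number of fissions plus the number of fusions.
    """
    g = graph.graph
    events: list[Event] = []
    for node in g.nodes():
        step, _ = node
        cx, cy = graph.centroid(node)
        clock = graph.t0 + step * graph.dt
        succ = list(g.successors(node))
        if len(succ) >= 2:
            events.append(
                Event(
                    kind="fission",
                    step=step,
                    clock_time=clock,
                    x=cx,
                    y=cy,
                    reference=graph.members(node),
                    branches=tuple(
                        sorted((graph.members(s) for s in succ), key=sorted)
                    ),
                )
            )
        pred = list(g.predecessors(node))
        if len(pred) >= 2:
            events.append(
                Event(
                    kind="fusion",
                    step=step,
                    clock_time=clock,
                    x=cx,
                    y=cy,
                    reference=graph.members(node),
                    branches=tuple(
                        sorted((graph.members(p) for p in pred), key=sorted)
                    ),
                )
            )
    out = EventList(events)
    undefined = sum(1 for ev in out if np.isnan(ev.x))
    if undefined:
        logger.warning("%d events have an undefined location (all members missing)", undefined)
    return out


def locate_event(event: Event, traj: TrajectorySet) -> tuple[float, float]:
    """Mean position at the event step of the reference group's present members.

    Returns a NaN pair (and logs a warning) when every reference member is
    missing at the step; the event itself is retained.
    """
    idx = [traj.index_of(i) for i in event.reference]
    pts = traj.xy[idx, event.step, :]
    if not np.isfinite(pts).any():
        logger.warning(
            "event at step %d has no located reference members", event.step
        )
        return (float("nan"), float("nan"))
    with np.errstate(invalid="ignore"):
        mx, my = np.nanmean(pts, axis=0)
    return (float(mx), float(my))


def detect_events(traj: TrajectorySet, timeline: GroupTimeline) -> EventList:
    """Convenience: build the group graph and extract its events."""
    return extract_events(build_group_graph(timeline, traj))
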