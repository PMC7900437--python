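"""Fibrillation-wave reconstruction, origin classification and re-entry.

Activation events form a spatiotemporal graph: vertices are
``(electrode, activation time)`` events, and two events at neighboring
electrodes are linked when their time difference is within the
relation's block limit (12 ms orthogonal / 17 ms oblique at 2.5 mm and
20 cm/s).  Fibrillation waves are the connected components of this
graph; their boundaries arise implicitly at the array edge and at
lines of conduction block.  Waves whose earliest activation lies on
the array periphery entered from outside the mapped area
("peripheral"); waves starting strictly inside it are breakthroughs.
Components spanning fewer than three distinct electrodes are treated
as noise-prone and filtered out.

A wave's conduction path is the minimum-spatial-length, time-forward
trajectory from its earliest to its latest event, each step implying a
conduction velocity at or above the block threshold.  A trajectory
revisiting an electrode after at least 75% of the mean AF cycle
length constitutes a local re-entry; revolutions are counted at the
most-revisited electrode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .conduction import block_limits
from .grid_io import ActivationSeries, ElectrodeGrid

__all__ = [
    "Wave",
    "ReentryEvent",
    "WaveIntegrityError",
    "reconstruct_waves",
    "classify_origin",
    "filter_waves",
    "normalize_counts",
    "conduction_path",
    "detect_reentries",
]

logger = logging.getLogger(__name__)

PERIPHERAL = "peripheral"
BREAKTHROUGH = "breakthrough"


class WaveIntegrityError(RuntimeError):
    """Raised when a wave violates a structural guarantee (no path)."""


@dataclass
class Wave:
    """A spatiotemporally connected set of activation events."""

    wave_id: int
    events: list  # [(electrode, at_ms)] sorted by (time, electrode)
    origin: str | None = None

    @property
    def earliest(self) -> tuple[int, float]:
        return self.events[0]

    @property
    def latest(self) -> tuple[int, float]:
        return self.events[-1]

    @property
    def n_electrodes(self) -> int:
        return len({e for e, _ in self.events})

    @property
    def t_start_ms(self) -> float:
        return self.events[0][1]

    @property
    def t_end_ms(self) -> float:
        return self.events[-1][1]


@dataclass
class ReentryEvent:
    """A conduction trajectory with qualifying self-intersections."""

    wave_id: int
    trajectory: list  # [(electrode, at_ms)]
    intersections: list  # [(electrode, t_prev, t_revisit)]
    n_revolutions: int
    t_start_ms: float
    t_end_ms: float


def _sort_key(grid: ElectrodeGrid):
    # earliest-tie order: time, then peripheral before interior, then id
    def key(ev):
        e, t = ev
        return (t, 0 if grid.is_peripheral(e) else 1, e)

    return key


def reconstruct_waves(
    series: ActivationSeries,
    grid: ElectrodeGrid,
    limits: Mapping[str, int] | None = None,
) -> list[Wave]:
    """Connected-component wave reconstruction from activation times.

    Vertices are activation events; an undirected edge joins events at
    neighboring electrodes whose time difference is within the
    relation's limit.  Returns waves ordered by earliest activation,
    with origin classes already assigned.
    """
    if limits is None:
        limits = block_limits(grid)
    g = nx.Graph()
    index: dict[int, tuple[np.ndarray, list]] = {}
    for e, t in series.times.items():
        nodes = [(e, float(tt)) for tt in t]
        g.add_nodes_from(nodes)
        index[e] = (t, nodes)
    for a, b, rel in grid.neighbor_pairs:
        if a not in index or b not in index:
            continue
        ta, nodes_a = index[a]
        tb, nodes_b = index[b]
        limit = limits[rel] + 1e-9
        lo = np.searchsorted(tb, ta - limit)
        hi = np.searchsorted(tb, ta + limit, side="right")
        for k in range(ta.size):
            for m in range(lo[k], hi[k]):
                g.add_edge(nodes_a[k], nodes_b[m])
    comps = [sorted(c, key=_sort_key(grid)) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (c[0][1], c[0][0]))
    waves = [Wave(wave_id=i, events=c) for i, c in enumerate(comps)]
    for w in waves:
        w.origin = classify_origin(w, grid)
    return waves


def classify_origin(wave: Wave, grid: ElectrodeGrid) -> str:
    """Peripheral if the earliest activation sits on the array edge.

    Ties in earliest time are broken toward peripheral: if any of the
    simultaneously earliest electrodes lies on the periphery the wave
    entered from outside the mapped area.
    """
    if not wave.events:
        raise ValueError("empty wave")
    t0 = wave.events[0][1]
    tied = [e for e, t in wave.events if abs(t - t0) <= 1e-9]
    peripheral = any(grid.is_peripheral(e) for e in tied)
    return PERIPHERAL if peripheral else BREAKTHROUGH


def filter_waves(waves: Sequence[Wave], min_electrodes: int = 3) -> list[Wave]:
    """Drop waves spanning fewer than ``min_electrodes`` distinct sites.

    Isolated activations of fewer than 3 adjacent electrodes are prone
    to noise or activation-time mis-assignment.
    """
    kept = [w for w in waves if w.n_electrodes >= min_electrodes]
    if len(kept) < len(waves):
        logger.info(
            "filter_waves: removed %d of %d waves (< %d electrodes)",
            len(waves) - len(kept), len(waves), min_electrodes,
        )
    return kept


def normalize_counts(
    waves: Sequence[Wave], window_ms: float, mean_afcl_ms: float
) -> dict:
    """Cycle-length-normalized wave statistics.

    ``waves_per_cycle = n_waves * mean_afcl / window`` (and likewise
    for breakthroughs); ``breakthrough_fraction`` is the share of
    breakthrough waves, ``None`` when there are no waves.
    """
    if window_ms <= 0 or mean_afcl_ms <= 0:
        raise ValueError("window and mean AFCL must be positive")
    n_waves = len(waves)
    n_bt = sum(w.origin == BREAKTHROUGH for w in waves)
    return {
        "n_waves": n_waves,
        "n_breakthroughs": n_bt,
        "waves_per_cycle": n_waves * mean_afcl_ms / window_ms,
        "breakthroughs_per_cycle": n_bt * mean_afcl_ms / window_ms,
        "breakthrough_fraction": (n_bt / n_waves) if n_waves else None,
    }


def _directed_wave_graph(wave: Wave, grid: ElectrodeGrid, limits) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(wave.events)
    by_electrode: dict[int, list] = {}
    for ev in wave.events:
        by_electrode.setdefault(ev[0], []).append(ev)
    for a, b, rel in grid.neighbor_pairs:
        if a not in by_electrode or b not in by_electrode:
            continue
        limit = limits[rel] + 1e-9
        dist = grid.neighbor_distance(rel)
        for ea in by_electrode[a]:
            for eb in by_electrode[b]:
                dt = eb[1] - ea[1]
                if abs(dt) > limit:
                    continue
                if dt > 0 or (dt == 0 and ea[0] < eb[0]):
                    g.add_edge(ea, eb, weight=dist)
                elif dt < 0 or (dt == 0 and eb[0] < ea[0]):
                    g.add_edge(eb, ea, weight=dist)
    return g


def conduction_path(
    wave: Wave,
    grid: ElectrodeGrid,
    limits: Mapping[str, int] | None = None,
    strict: bool = True,
) -> list:
    """Shortest continuous trajectory through a wave.

    Directed event graph: an edge runs from the earlier to the later
    of two neighboring events when their delay is within the block
    limit (each step implies an apparent velocity at or above the
    block threshold); simultaneous events are oriented by electrode
    index.  The trajectory is the minimum-total-spatial-length path
    from the wave's earliest to its latest event.  If the latest event
    is not reachable (possible when fronts fuse), ``strict=True``
    raises :class:`WaveIntegrityError`; otherwise the path runs to the
    latest reachable event.
    """
    if len(wave.events) < 2:
        return list(wave.events)
    if limits is None:
        limits = block_limits(grid)
    g = _directed_wave_graph(wave, grid, limits)
    source = wave.earliest
    target = wave.latest
    try:
        return nx.dijkstra_path(g, source, target, weight="weight")
    except nx.NetworkXNoPath:
        if strict:
            raise WaveIntegrityError(
                f"wave {wave.wave_id}: latest event unreachable from earliest"
            )
        lengths = nx.single_source_dijkstra_path_length(g, source, weight="weight")
        target = max(lengths, key=lambda ev: (ev[1], -lengths[ev]))
        return nx.dijkstra_path(g, source, target, weight="weight")


def _self_intersections(trajectory: list, min_gap_ms: float):
    last_visit: dict[int, float] = {}
    hits: dict[int, list] = {}
    for e, t in trajectory:
        if e in last_visit and t - last_visit[e] >= min_gap_ms - 1e-9:
            hits.setdefault(e, []).append((e, last_visit[e], t))
        last_visit[e] = t
    return hits


def detect_reentries(
    waves: Sequence[Wave],
    grid: ElectrodeGrid,
    limits: Mapping[str, int] | None = None,
    mean_afcl_ms: float = None,
    window_ms: float | None = None,
) -> tuple[list[ReentryEvent], dict]:
    """Local re-entry detection on wave conduction paths.

    A wave is a local re-entry when its trajectory revisits an
    electrode after at least 75% of the mean AF cycle length;
    ``n_revolutions`` counts qualifying revisits at the most-revisited
    electrode.  The summary reports the percentage of the analysis
    window during which at least one re-entrant circuit was present
    (union of qualifying trajectories' time spans) and the mean of the
    per-event maximal revolution counts.
    """
    if mean_afcl_ms is None or mean_afcl_ms <= 0:
        raise ValueError("mean_afcl_ms must be positive")
    if limits is None:
        limits = block_limits(grid)
    min_gap = 0.75 * mean_afcl_ms
    events: list[ReentryEvent] = []
    for w in waves:
        if len(w.events) < 2:
            continue
        traj = conduction_path(w, grid, limits, strict=False)
        hits = _self_intersections(traj, min_gap)
        if not hits:
            continue
        n_rev = max(len(v) for v in hits.values())
        intersections = [h for v in hits.values() for h in v]
        events.append(
            ReentryEvent(
                wave_id=w.wave_id,
                trajectory=traj,
                intersections=sorted(intersections, key=lambda x: x[2]),
                n_revolutions=n_rev,
                t_start_ms=traj[0][1],
                t_end_ms=traj[-1][1],
            )
        )
    if window_ms is None:
        if waves:
            window_ms = max(w.t_end_ms for w in waves) - min(w.t_start_ms for w in waves)
        else:
            window_ms = 0.0
    spans = sorted((ev.t_start_ms, ev.t_end_ms) for ev in events)
    covered = 0.0
    cur = None
    for lo, hi in spans:
        if cur is None or lo > cur[1]:
            if cur is not None:
                covered += cur[1] - cur[0]
            cur = [lo, hi]
        else:
            cur[1] = max(cur[1], hi)
    if cur is not None:
        covered += cur[1] - cur[0]
    summary = {
        "n_reentries": len(events),
        "percent_time_present": (100.0 * covered / window_ms) if window_ms else 0.0,
        "mean_max_revolutions": (
            float(np.mean([ev.n_revolutions for ev in events])) if events else 0.0
        ),
    }
    return events, summary
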