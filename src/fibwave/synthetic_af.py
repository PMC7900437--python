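"""Ground-truth generator for atrial-propagation and electrogram fixtures.

Activation patterns are produced by an earliest-arrival (graph
geodesic) propagation model on the 8-neighbor electrode lattice:
each non-blocked neighbor link is traversed in ``length / speed`` ms,
wavefronts from multiple sources compete by minimum arrival time, and
a per-electrode refractory floor merges colliding fronts into one
activation per cycle.  This is deliberately not a PDE/eikonal tissue
model — it produces exactly the observables the analysis consumes
(activation times) together with exact ground truth for every event:
winning source, wave membership, origin class and per-electrode cycle
length.

Scenarios cover planar entry waves, colliding waves, focal
breakthroughs, conduction-block lines, rotors (spiral re-entry) and
compound AF episodes.  :func:`synthesize_egms` turns an activation
series into a multichannel unipolar electrogram recording with a
biphasic (derivative-of-Gaussian) deflection per activation, a
channel-identical ventricular QRST far-field, a clean ventricular
reference channel, optional first-order acquisition filters
(0.56 Hz high-pass, 408 Hz low-pass) and additive Gaussian noise.

Ground-truth wave labels are defined by applying the block-limit
boundary rule to the noiseless true activation times (waves are a
construct of the observed activation map); they are computed here
with a scipy sparse connected-components code path that is
independent of the analysis module's reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra

from .conduction import BLOCK_VELOCITY_CM_S, block_limits
from .grid_io import OBLIQUE, ORTHOGONAL, ActivationSeries, EgmRecording, ElectrodeGrid

__all__ = [
    "Source",
    "Scenario",
    "ScenarioTruth",
    "edge_sites",
    "simulate_arrival_times",
    "simulate_rotor",
    "simulate_af_episode",
    "random_block_wall",
    "qrst_template",
    "synthesize_egms",
    "synthesize_ecg",
]

PERIPHERAL = "peripheral"
BREAKTHROUGH = "breakthrough"
ROTOR = "rotor"


@dataclass(frozen=True)
class Source:
    """One wavefront source: a set of seed electrodes firing together.

    ``kind`` is ``"planar"`` (seeds along an array edge) or
    ``"focal"`` (single interior seed).  A source may refire
    periodically: ``n_cycles`` firings separated by ``period_ms``.
    """

    kind: str
    sites: tuple
    onset_ms: float = 0.0
    period_ms: float | None = None
    n_cycles: int = 1

    def __post_init__(self):
        if self.kind not in ("planar", "focal"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        if not self.sites:
            raise ValueError("source needs at least one seed electrode")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.n_cycles > 1 and (self.period_ms is None or self.period_ms <= 0):
            raise ValueError("periodic source needs period_ms > 0")


@dataclass
class Scenario:
    """Propagation scenario: grid, sources, speed, block set, duration.

    ``speed_cm_s`` is a scalar or an ``(vx, vy)`` pair; with a pair the
    speed of a link at angle ``theta`` to the x-axis is the elliptical
    ``sqrt((vx cos)^2 + (vy sin)^2)``, giving a fixed anisotropy ratio.
    ``blocked_edges`` are unordered electrode-id pairs taken from the
    grid's neighbor relation.
    """

    grid: ElectrodeGrid
    sources: list
    speed_cm_s: float | tuple = 100.0
    blocked_edges: frozenset = frozenset()
    duration_ms: float | None = None
    refractory_floor_ms: float = 40.0
    seed: int | None = None

    def __post_init__(self):
        speeds = np.atleast_1d(np.asarray(self.speed_cm_s, dtype=float))
        if np.any(speeds <= 0):
            raise ValueError("speeds must be positive")
        if not self.sources:
            raise ValueError("scenario needs at least one source")
        neighbor_set = {frozenset((i, j)) for i, j, _ in self.grid.neighbor_pairs}
        self.blocked_edges = frozenset(frozenset(e) for e in self.blocked_edges)
        if not self.blocked_edges <= neighbor_set:
            raise ValueError("blocked_edges must be a subset of the neighbor relation")


@dataclass
class ScenarioTruth:
    """Exact per-event ground truth for a generated activation series.

    ``events`` is a tidy frame with columns ``electrode, at_ms,
    source_id, cycle, wave_id, origin_class``; ``waves`` summarizes
    each truth wave (id, origin class, distinct-electrode count, time
    span).  ``unreachable`` lists electrodes enclosed by block that no
    wavefront could reach.
    """

    events: pd.DataFrame
    waves: pd.DataFrame
    blocked_edges: tuple = ()
    unreachable: tuple = ()
    cycle_length_ms: dict = field(default_factory=dict)

    def n_waves(self, min_electrodes: int = 3) -> int:
        return int((self.waves["n_electrodes"] >= min_electrodes).sum())

    def n_breakthroughs(self, min_electrodes: int = 3) -> int:
        keep = self.waves["n_electrodes"] >= min_electrodes
        return int((keep & (self.waves["origin_class"] == BREAKTHROUGH)).sum())


def edge_sites(grid: ElectrodeGrid, side: str) -> tuple:
    """Active electrodes along one array edge ('left'/'right'/'top'/'bottom')."""
    rows = grid.electrode_rc[:, 0]
    cols = grid.electrode_rc[:, 1]
    if side == "left":
        sel = cols == cols.min()
    elif side == "right":
        sel = cols == cols.max()
    elif side == "bottom":
        sel = rows == rows.min()
    elif side == "top":
        sel = rows == rows.max()
    else:
        raise ValueError(f"unknown side {side!r}")
    return tuple(np.nonzero(sel)[0].tolist())


def _edge_speed(speed_cm_s, dx: float, dy: float) -> float:
    v = np.atleast_1d(np.asarray(speed_cm_s, dtype=float))
    if v.size == 1:
        return float(v[0])
    norm = math.hypot(dx, dy)
    c, s = dx / norm, dy / norm
    return math.hypot(v[0] * c, v[1] * s)


def _travel_graph(grid: ElectrodeGrid, speed_cm_s, blocked_edges) -> sparse.csr_matrix:
    """Sparse matrix of link traversal times (ms) over non-blocked edges."""
    rows, cols, w = [], [], []
    blocked = {frozenset(e) for e in blocked_edges}
    for i, j, rel in grid.neighbor_pairs:
        if frozenset((i, j)) in blocked:
            continue
        dx, dy = grid.coordinates[j] - grid.coordinates[i]
        dist = grid.neighbor_distance(rel)
        t = dist / (_edge_speed(speed_cm_s, dx, dy) / 100.0)
        rows += [i, j]
        cols += [j, i]
        w += [t, t]
    n = grid.n_active
    return sparse.csr_matrix((w, (rows, cols)), shape=(n, n))


def _truth_wave_table(grid, electrodes, times, limits, origin_override=None):
    """Wave labels for truth events: connected components of the event
    graph under the block-limit rule, via scipy csgraph (independent of
    the analysis-module reconstruction)."""
    n = len(electrodes)
    if n == 0:
        empty_waves = pd.DataFrame(
            columns=["wave_id", "origin_class", "n_electrodes", "t_start_ms", "t_end_ms"]
        )
        return np.empty(0, dtype=int), np.empty(0, dtype=object), empty_waves
    order = np.lexsort((times, electrodes))
    idx_by_electrode: dict[int, np.ndarray] = {}
    for e in np.unique(electrodes):
        sel = order[electrodes[order] == e]
        idx_by_electrode[int(e)] = sel
    rows, cols = [], []
    for a, b, rel in grid.neighbor_pairs:
        ia = idx_by_electrode.get(a)
        ib = idx_by_electrode.get(b)
        if ia is None or ib is None:
            continue
        limit = limits[rel] + 1e-9
        tb = times[ib]
        lo = np.searchsorted(tb, times[ia] - limit)
        hi = np.searchsorted(tb, times[ia] + limit, side="right")
        for k, (l, h) in enumerate(zip(lo, hi)):
            for m in range(l, h):
                rows.append(ia[k])
                cols.append(ib[m])
    adj = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    # relabel waves by earliest event time; classify origin at earliest event
    wave_rows = []
    first_time = np.full(n_comp, np.inf)
    for k in range(n):
        first_time[labels[k]] = min(first_time[labels[k]], times[k])
    new_id = {old: rank for rank, old in enumerate(np.argsort(first_time, kind="stable"))}
    wave_ids = np.array([new_id[l] for l in labels], dtype=int)
    origin = np.empty(n, dtype=object)
    for w in range(n_comp):
        members = np.nonzero(wave_ids == w)[0]
        t_w = times[members]
        t_min = t_w.min()
        earliest = members[np.isclose(t_w, t_min, atol=1e-9)]
        if origin_override is not None:
            cls = origin_override
        else:
            peripheral = any(grid.is_peripheral(int(electrodes[m])) for m in earliest)
            cls = PERIPHERAL if peripheral else BREAKTHROUGH
        origin[members] = cls
        wave_rows.append(
            (w, cls, len(np.unique(electrodes[members])), float(t_min), float(t_w.max()))
        )
    waves = pd.DataFrame(
        wave_rows,
        columns=["wave_id", "origin_class", "n_electrodes", "t_start_ms", "t_end_ms"],
    ).sort_values("wave_id", ignore_index=True)
    return wave_ids, origin, waves


def _cycle_lengths(times_by_electrode: dict) -> dict:
    return {
        e: float(np.median(np.diff(t)))
        for e, t in times_by_electrode.items()
        if len(t) >= 2
    }


def _assemble_truth(
    grid, kept, limits, blocked_edges, unreachable, origin_override=None
):
    """Build (ActivationSeries-ready dict, ScenarioTruth) from kept events.

    ``kept`` maps electrode -> list of (t, source_id, cycle)."""
    electrodes, times, src, cyc = [], [], [], []
    for e in sorted(kept):
        for t, s, c in kept[e]:
            electrodes.append(e)
            times.append(t)
            src.append(s)
            cyc.append(c)
    electrodes = np.asarray(electrodes, dtype=int)
    times = np.asarray(times, dtype=float)
    wave_ids, origin, waves = _truth_wave_table(
        grid, electrodes, times, limits, origin_override
    )
    events = pd.DataFrame(
        {
            "electrode": electrodes,
            "at_ms": times,
            "source_id": np.asarray(src, dtype=int),
            "cycle": np.asarray(cyc, dtype=int),
            "wave_id": wave_ids,
            "origin_class": origin,
        }
    ).sort_values(["at_ms", "electrode"], ignore_index=True)
    series_times = {
        e: np.sort(times[electrodes == e]) for e in np.unique(electrodes)
    }
    truth = ScenarioTruth(
        events=events,
        waves=waves,
        blocked_edges=tuple(tuple(sorted(e)) for e in blocked_edges),
        unreachable=tuple(unreachable),
        cycle_length_ms=_cycle_lengths(series_times),
    )
    return series_times, truth


def simulate_arrival_times(scenario: Scenario) -> tuple[ActivationSeries, ScenarioTruth]:
    """Earliest-arrival activation times for a multi-source scenario.

    Arrival times are graph geodesics over non-blocked neighbor links
    (link time = length / speed); with several sources each electrode
    takes the minimum arrival per cycle and the truth records the
    winning source.  Candidate activations arriving within the
    refractory floor of an accepted one are absorbed (wavefront
    collision/fusion).  Electrodes unreachable from every source are
    reported in ``truth.unreachable``.
    """
    grid = scenario.grid
    graph = _travel_graph(grid, scenario.speed_cm_s, scenario.blocked_edges)
    base = np.empty((len(scenario.sources), grid.n_active))
    for s, source in enumerate(scenario.sources):
        d = dijkstra(graph, directed=False, indices=list(source.sites))
        base[s] = source.onset_ms + d.min(axis=0)
    unreachable = np.nonzero(np.all(np.isinf(base), axis=0))[0]

    duration = scenario.duration_ms
    if duration is None:
        finite = base[np.isfinite(base)]
        last_onset = max(
            src.onset_ms + (src.n_cycles - 1) * (src.period_ms or 0.0)
            for src in scenario.sources
        )
        duration = (finite.max() if finite.size else 0.0) + (
            last_onset - min(src.onset_ms for src in scenario.sources)
        ) + 1.0

    kept: dict[int, list] = {}
    for e in range(grid.n_active):
        cands = []
        for s, source in enumerate(scenario.sources):
            if not np.isfinite(base[s, e]):
                continue
            for k in range(source.n_cycles):
                t = base[s, e] + k * (source.period_ms or 0.0)
                if t <= duration + 1e-9:
                    cands.append((t, s, k))
        cands.sort()
        acc = []
        for t, s, k in cands:
            if not acc or t - acc[-1][0] >= scenario.refractory_floor_ms - 1e-9:
                acc.append((t, s, k))
        if acc:
            kept[e] = acc

    limits = block_limits(grid)
    series_times, truth = _assemble_truth(
        grid, kept, limits, scenario.blocked_edges, unreachable
    )
    window_start = min(src.onset_ms for src in scenario.sources)
    series = ActivationSeries(
        series_times,
        window_start_ms=window_start,
        window_end_ms=max(duration, window_start + 1.0),
        refractory_floor_ms=scenario.refractory_floor_ms,
    )
    return series, truth


def simulate_rotor(
    grid: ElectrodeGrid,
    core: int,
    period_ms: float,
    n_cycles: int,
    onset_ms: float = 0.0,
    chirality: int = 1,
) -> tuple[ActivationSeries, ScenarioTruth]:
    """Idealized rotor: phase-of-angle activation about an interior core.

    Electrode ``e`` at polar angle ``phi`` about the core activates at
    ``onset + n * period + period * phase / (2 pi)`` in cycle ``n``,
    with ``phase = (chirality * phi) mod 2 pi``; every electrode's
    cycle length is exactly ``period_ms``.  The core electrode itself
    is silent (functional block at the rotor pivot).
    """
    if period_ms <= 0 or n_cycles < 1:
        raise ValueError("period_ms > 0 and n_cycles >= 1 required")
    if chirality not in (1, -1):
        raise ValueError("chirality must be +1 or -1")
    if grid.is_peripheral(core):
        raise ValueError("rotor core must be strictly interior")
    xy = grid.coordinates - grid.coordinates[core]
    phi = np.arctan2(xy[:, 1], xy[:, 0])
    phase = np.mod(chirality * phi, 2.0 * math.pi)
    kept: dict[int, list] = {}
    for e in range(grid.n_active):
        if e == core:
            continue
        t0 = onset_ms + period_ms * phase[e] / (2.0 * math.pi)
        kept[e] = [(t0 + n * period_ms, 0, n) for n in range(n_cycles)]
    limits = block_limits(grid)
    series_times, truth = _assemble_truth(
        grid, kept, limits, (), (), origin_override=ROTOR
    )
    floor = min(40.0, period_ms)
    series = ActivationSeries(
        series_times,
        window_start_ms=onset_ms,
        window_end_ms=onset_ms + (n_cycles + 1) * period_ms,
        refractory_floor_ms=floor,
    )
    return series, truth


def random_block_wall(rng: np.random.Generator, grid: ElectrodeGrid, length: int = 5):
    """A random straight conduction-block wall.

    Returns the set of neighbor links severed by a line segment of
    ``length`` lattice steps placed horizontally or vertically at a
    random interior position (orthogonal links crossing the wall plus
    the oblique links spanning it).
    """
    neighbor_set = {frozenset((i, j)): rel for i, j, rel in grid.neighbor_pairs}
    index = -np.ones((grid.n_rows, grid.n_cols), dtype=int)
    for k, (r, c) in enumerate(grid.electrode_rc):
        index[r, c] = k
    horizontal = rng.random() < 0.5
    blocked = set()
    if horizontal:
        r = int(rng.integers(1, grid.n_rows - 1))
        c0 = int(rng.integers(0, max(1, grid.n_cols - length)))
        for c in range(c0, min(c0 + length, grid.n_cols)):
            for dc in (-1, 0, 1):
                cc = c + dc
                if 0 <= cc < grid.n_cols and index[r - 1, c] >= 0 and index[r, cc] >= 0:
                    e = frozenset((index[r - 1, c], index[r, cc]))
                    if e in neighbor_set:
                        blocked.add(e)
    else:
        c = int(rng.integers(1, grid.n_cols - 1))
        r0 = int(rng.integers(0, max(1, grid.n_rows - length)))
        for r in range(r0, min(r0 + length, grid.n_rows)):
            for dr in (-1, 0, 1):
                rr = r + dr
                if 0 <= rr < grid.n_rows and index[r, c - 1] >= 0 and index[rr, c] >= 0:
                    e = frozenset((index[r, c - 1], index[rr, c]))
                    if e in neighbor_set:
                        blocked.add(e)
    return blocked


def simulate_af_episode(
    grid: ElectrodeGrid,
    mean_afcl_ms: float = 185.0,
    focal_rate_per_s: float = 1.0,
    n_block_lines: int = 2,
    speed_cm_s=80.0,
    jitter_sd_ms: float = 5.0,
    duration_ms: float = 4000.0,
    seed: int | None = None,
    block_line_length: int = 5,
    refractory_floor_ms: float = 40.0,
) -> tuple[ActivationSeries, ScenarioTruth]:
    """Compound AF episode with exact ground truth.

    Cycle by cycle (period ``mean_afcl_ms`` with Gaussian interval
    jitter), a planar wavefront is launched from a random array edge;
    focal breakthroughs arrive as a Poisson process at
    ``focal_rate_per_s`` from random interior sites; each cycle draws
    ``n_block_lines`` fresh random block walls.  All randomness comes
    from ``seed``; the truth enumerates every wave with its origin
    class and the per-electrode cycle lengths.
    """
    if duration_ms < 2.0 * mean_afcl_ms:
        raise ValueError("duration must cover at least two mean cycles")
    if mean_afcl_ms <= 0 or focal_rate_per_s < 0 or n_block_lines < 0:
        raise ValueError("parameter out of range")
    if jitter_sd_ms < 0:
        raise ValueError("jitter_sd_ms must be >= 0")
    rng = np.random.default_rng(seed)

    onsets = []
    t = 1.0
    while t < duration_ms - 0.3 * mean_afcl_ms:
        onsets.append(t)
        step = mean_afcl_ms + (rng.normal(0.0, jitter_sd_ms) if jitter_sd_ms else 0.0)
        t += max(step, 0.5 * mean_afcl_ms)

    n_focal = rng.poisson(focal_rate_per_s * duration_ms / 1000.0)
    interior = sorted(set(range(grid.n_active)) - set(grid.periphery))
    focal_times = np.sort(rng.uniform(0.0, duration_ms, size=n_focal))
    focal_sites = rng.choice(interior, size=n_focal) if interior else np.empty(0, int)

    sides = ("left", "right", "top", "bottom")
    all_blocked = set()
    kept: dict[int, list] = {}
    last_time = {e: -np.inf for e in range(grid.n_active)}
    onset_arr = np.asarray(onsets)
    source_id = 0
    for k, t_k in enumerate(onsets):
        blocked = set()
        for _ in range(n_block_lines):
            blocked |= random_block_wall(rng, grid, block_line_length)
        all_blocked |= blocked
        graph = _travel_graph(grid, speed_cm_s, blocked)

        seeds = [(edge_sites(grid, sides[rng.integers(4)]), t_k)]
        for ft, fsite in zip(focal_times, focal_sites):
            if np.argmin(np.abs(onset_arr - ft)) == k:
                seeds.append(((int(fsite),), float(ft)))
        arrivals = np.empty((len(seeds), grid.n_active))
        for s, (sites, onset) in enumerate(seeds):
            d = dijkstra(graph, directed=False, indices=list(sites))
            arrivals[s] = onset + d.min(axis=0)
        winner = np.argmin(arrivals, axis=0)
        t_win = arrivals[winner, np.arange(grid.n_active)]
        for e in range(grid.n_active):
            te = t_win[e]
            if not np.isfinite(te) or te > duration_ms:
                continue
            if te - last_time[e] >= refractory_floor_ms - 1e-9:
                kept.setdefault(e, []).append((float(te), source_id + int(winner[e]), k))
                last_time[e] = te
        source_id += len(seeds)

    limits = block_limits(grid)
    series_times, truth = _assemble_truth(grid, kept, limits, all_blocked, ())
    series = ActivationSeries(
        series_times, 0.0, duration_ms, refractory_floor_ms=refractory_floor_ms
    )
    return series, truth


# ---------------------------------------------------------------------------
# electrogram synthesis


def _deflection(tau_ms: np.ndarray, sigma_ms: float, pp_mv: float) -> np.ndarray:
    """Biphasic derivative-of-Gaussian deflection, peak-to-peak ``pp_mv``.

    Steepest negative slope falls exactly at ``tau = 0`` (the local
    activation time)."""
    c = pp_mv * math.exp(0.5) / (2.0 * sigma_ms)
    return -c * tau_ms * np.exp(-(tau_ms**2) / (2.0 * sigma_ms**2))


def qrst_template(
    fs_hz: float = 1039.0, amplitude_mv: float = 1.0
) -> tuple[np.ndarray, dict]:
    """Synthetic ventricular QRST far-field waveform (600 ms support).

    A Gaussian R wave (sigma 15 ms, centered 150 ms into the template)
    followed by a Gaussian T wave (sigma 40 ms at 450 ms).  Returns the
    sampled template and its analytic fiducials; under the
    tangent-method definition the T end of a Gaussian T wave of width
    sigma falls exactly 2 sigma after the T peak.
    """
    support_ms = 600.0
    r_ms, r_sigma = 150.0, 15.0
    t_ms, t_sigma = 450.0, 40.0
    t_amp = 0.35
    tau = np.arange(int(round(support_ms * fs_hz / 1000.0))) * 1000.0 / fs_hz
    wave = amplitude_mv * (
        np.exp(-((tau - r_ms) ** 2) / (2 * r_sigma**2))
        + t_amp * np.exp(-((tau - t_ms) ** 2) / (2 * t_sigma**2))
    )
    # 5%-of-R-amplitude threshold crossings of the Gaussian R wave
    half_qrs = r_sigma * math.sqrt(2.0 * math.log(20.0))
    truth = {
        "support_ms": support_ms,
        "r_peak_ms": r_ms,
        "q_onset_ms": r_ms - half_qrs,
        "s_offset_ms": r_ms + half_qrs,
        "qrs_ms": 2.0 * half_qrs,
        "t_peak_ms": t_ms,
        "t_sigma_ms": t_sigma,
        "t_end_ms": t_ms + 2.0 * t_sigma,
        "qt_ms": t_ms + 2.0 * t_sigma - (r_ms - half_qrs),
    }
    return wave, truth


def _acquisition_filter(x: np.ndarray, fs_hz: float) -> np.ndarray:
    """First-order 0.56 Hz high-pass then 408 Hz low-pass (causal)."""
    b, a = sps.butter(1, 0.56, btype="highpass", fs=fs_hz)
    x = sps.lfilter(b, a, x, axis=-1)
    if 408.0 < fs_hz / 2.0:
        b, a = sps.butter(1, 408.0, btype="lowpass", fs=fs_hz)
        x = sps.lfilter(b, a, x, axis=-1)
    return x


def synthesize_egms(
    series: ActivationSeries,
    grid: ElectrodeGrid,
    fs_hz: float = 1039.0,
    deflection_sigma_ms: float = 2.0,
    deflection_pp_mv: float = 1.0,
    farfield_rr_ms: float = 1200.0,
    farfield_amplitude_mv: float = 0.5,
    farfield_first_beat_ms: float = 400.0,
    per_beat_scales=None,
    noise_sd_mv: float = 0.0,
    acquisition_filters: bool = False,
    include_reference: bool = True,
    pad_ms: float = 60.0,
    seed: int | None = None,
) -> tuple[EgmRecording, dict]:
    """Unipolar electrogram synthesis from an activation series.

    Each activation contributes a biphasic derivative-of-Gaussian
    deflection centered at its true activation time; an identical QRST
    far-field waveform is added to every electrode channel at regular
    ventricular beat times (optionally scaled per beat), and a clean
    ventricular reference channel is appended.  Deflections closer
    than the template support are summed and flagged in the returned
    info dict.  Returns ``(recording, info)`` with info containing
    ``beat_times_ms``, per-beat scales and overlap flags.
    """
    rng = np.random.default_rng(seed)
    t_end = series.window_end_ms + pad_ms
    n_samples = int(round(t_end * fs_hz / 1000.0))
    t_axis = np.arange(n_samples) * 1000.0 / fs_hz
    n_el = grid.n_active
    n_ch = n_el + (1 if include_reference else 0)
    signals = np.zeros((n_ch, n_samples))

    half = 4.0 * deflection_sigma_ms
    overlaps = []
    for e, t in series.times.items():
        if t.size > 1 and np.any(np.diff(t) < 2 * half):
            for k in np.nonzero(np.diff(t) < 2 * half)[0]:
                overlaps.append((int(e), float(t[k]), float(t[k + 1])))
        for at in t:
            lo = max(0, int(math.floor((at - half) * fs_hz / 1000.0)))
            hi = min(n_samples, int(math.ceil((at + half) * fs_hz / 1000.0)) + 1)
            signals[e, lo:hi] += _deflection(
                t_axis[lo:hi] - at, deflection_sigma_ms, deflection_pp_mv
            )

    qrst, qrst_truth = qrst_template(fs_hz, amplitude_mv=1.0)
    beat_times = np.arange(farfield_first_beat_ms, t_end - 1.0, farfield_rr_ms)
    if per_beat_scales is None:
        scales = np.ones(beat_times.size)
    else:
        scales = np.asarray(per_beat_scales, dtype=float)[: beat_times.size]
        if scales.size < beat_times.size:
            scales = np.pad(scales, (0, beat_times.size - scales.size), constant_values=1.0)
    for bt, sc in zip(beat_times, scales):
        lo = int(round(bt * fs_hz / 1000.0))
        hi = min(n_samples, lo + qrst.size)
        if lo >= n_samples:
            continue
        seg = qrst[: hi - lo]
        signals[:n_el, lo:hi] += farfield_amplitude_mv * sc * seg
        if include_reference:
            signals[n_el, lo:hi] += sc * seg

    if acquisition_filters:
        signals = _acquisition_filter(signals, fs_hz)
    if noise_sd_mv > 0:
        signals = signals + rng.normal(0.0, noise_sd_mv, signals.shape)

    channel_map = np.arange(n_ch)
    ref = None
    if include_reference:
        channel_map[n_el] = -1
        ref = n_el
    rec = EgmRecording(
        signals=signals,
        sampling_rate_hz=fs_hz,
        channel_map=channel_map,
        reference_channel=ref,
    )
    info = {
        "beat_times_ms": beat_times,
        "beat_scales": scales,
        "qrst_truth": qrst_truth,
        "overlapping_events": overlaps,
        "farfield_amplitude_mv": farfield_amplitude_mv,
    }
    return rec, info


def synthesize_ecg(
    rr_ms: float = 1200.0,
    n_beats: int = 12,
    fs_hz: float = 1039.0,
    amplitude_mv: float = 1.0,
    noise_sd_mv: float = 0.0,
    first_beat_ms: float = 300.0,
    seed: int | None = None,
) -> tuple[np.ndarray, float, dict]:
    """Single-channel surface-ECG-like trace built from the QRST template.

    Returns ``(signal, fs_hz, truth)`` where truth carries the beat
    times and the template's analytic fiducials (R peak, Q onset,
    S offset, tangent-method T end).
    """
    qrst, truth = qrst_template(fs_hz, amplitude_mv)
    dur_ms = first_beat_ms + n_beats * rr_ms + 200.0
    n = int(round(dur_ms * fs_hz / 1000.0))
    x = np.zeros(n)
    beat_times = first_beat_ms + rr_ms * np.arange(n_beats)
    for bt in beat_times:
        lo = int(round(bt * fs_hz / 1000.0))
        hi = min(n, lo + qrst.size)
        x[lo:hi] += qrst[: hi - lo]
    if noise_sd_mv > 0:
        x += np.random.default_rng(seed).normal(0.0, noise_sd_mv, n)
    truth = dict(truth)
    truth["beat_times_ms"] = beat_times
    truth["r_peak_times_ms"] = beat_times + truth["r_peak_ms"]
    return x, fs_hz, truth
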