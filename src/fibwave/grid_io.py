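"""Electrode-array geometry and the core data containers.

The mapping hardware is a rectangular lattice of unipolar contact
electrodes (the reference device carries 249 electrodes at 2.5 mm
inter-electrode distance).  Everything downstream — block
classification, plane-fit conduction velocity, wave reconstruction —
is phrased in terms of the lattice neighbor relation: up to eight
neighbors per electrode, four orthogonal at distance ``spacing_mm``
and four oblique at ``spacing_mm * sqrt(2)``.

This module defines :class:`ElectrodeGrid`, :class:`ActivationSeries`
and :class:`EgmRecording` together with their plain-text/array file
formats (CSV activation maps, ``.npy`` + JSON-sidecar recordings,
JSON grid descriptions).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ElectrodeGrid",
    "ActivationSeries",
    "EgmRecording",
    "GridError",
    "build_grid",
    "default_mapping_grid",
    "save_grid",
    "load_grid",
    "save_activation_map",
    "load_activation_map",
    "save_recording",
    "load_recording",
]

ORTHOGONAL = "orthogonal"
OBLIQUE = "oblique"

#: lattice offsets of the 8-neighborhood, (drow, dcol, relation)
_NEIGHBOR_OFFSETS = [
    (-1, 0, ORTHOGONAL),
    (1, 0, ORTHOGONAL),
    (0, -1, ORTHOGONAL),
    (0, 1, ORTHOGONAL),
    (-1, -1, OBLIQUE),
    (-1, 1, OBLIQUE),
    (1, -1, OBLIQUE),
    (1, 1, OBLIQUE),
]


class GridError(ValueError):
    """Raised for invalid grid geometry or container violations."""


@dataclass(frozen=True)
class ElectrodeGrid:
    """Rectangular electrode lattice with an active-site mask.

    Active electrodes are numbered ``0..n_active-1`` in row-major
    order over active lattice sites.  Coordinates are
    electrode-centered, x to the right (columns), y upward (rows),
    in millimetres.

    Attributes
    ----------
    n_rows, n_cols : int
        Lattice dimensions.
    spacing_mm : float
        Inter-electrode distance along rows/columns (orthogonal
        neighbor distance); oblique neighbors sit at
        ``spacing_mm * sqrt(2)``.
    active_mask : ndarray of bool, shape (n_rows, n_cols)
        True where an electrode is present.
    regions : tuple of str
        Optional region tag per active electrode (e.g. ``"RA"``).
    """

    n_rows: int
    n_cols: int
    spacing_mm: float
    active_mask: np.ndarray
    regions: tuple = ()
    # derived, filled in __post_init__
    electrode_rc: np.ndarray = field(default=None, repr=False)
    coordinates: np.ndarray = field(default=None, repr=False)
    neighbor_pairs: tuple = field(default=None, repr=False)
    periphery: frozenset = field(default=None, repr=False)

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridError("grid must have at least one row and column")
        if self.spacing_mm <= 0:
            raise GridError("spacing_mm must be positive")
        mask = np.asarray(self.active_mask, dtype=bool)
        if mask.shape != (self.n_rows, self.n_cols):
            raise GridError(
                f"mask shape {mask.shape} does not match "
                f"({self.n_rows}, {self.n_cols})"
            )
        if not mask.any():
            raise GridError("grid has no active electrodes")
        object.__setattr__(self, "active_mask", mask)

        rows, cols = np.nonzero(mask)
        rc = np.column_stack([rows, cols])
        object.__setattr__(self, "electrode_rc", rc)
        xy = np.column_stack([cols, rows]).astype(float) * self.spacing_mm
        object.__setattr__(self, "coordinates", xy)

        index = -np.ones((self.n_rows, self.n_cols), dtype=int)
        index[rows, cols] = np.arange(len(rows))

        pairs = []
        n_neighbors = np.zeros(len(rows), dtype=int)
        for i, (r, c) in enumerate(rc):
            for dr, dc, rel in _NEIGHBOR_OFFSETS:
                rr, cc = r + dr, c + dc
                if 0 <= rr < self.n_rows and 0 <= cc < self.n_cols and mask[rr, cc]:
                    j = index[rr, cc]
                    n_neighbors[i] += 1
                    if j > i:
                        pairs.append((i, j, rel))
        object.__setattr__(self, "neighbor_pairs", tuple(pairs))
        object.__setattr__(
            self, "periphery", frozenset(np.nonzero(n_neighbors < 8)[0].tolist())
        )
        if self.regions:
            if len(self.regions) != len(rows):
                raise GridError("regions length must equal number of active electrodes")
            object.__setattr__(self, "regions", tuple(self.regions))

    @property
    def n_active(self) -> int:
        return len(self.electrode_rc)

    def neighbor_distance(self, relation: str) -> float:
        if relation == ORTHOGONAL:
            return self.spacing_mm
        if relation == OBLIQUE:
            return self.spacing_mm * math.sqrt(2.0)
        raise GridError(f"unknown neighbor relation {relation!r}")

    def neighbors_of(self, electrode: int):
        """List of ``(neighbor_id, relation)`` for one electrode."""
        out = []
        for i, j, rel in self.neighbor_pairs:
            if i == electrode:
                out.append((j, rel))
            elif j == electrode:
                out.append((i, rel))
        return out

    def region_of(self, electrode: int) -> str:
        return self.regions[electrode] if self.regions else ""

    def is_peripheral(self, electrode: int) -> bool:
        return electrode in self.periphery


def build_grid(
    n_rows: int,
    n_cols: int,
    spacing_mm: float,
    active_mask=None,
    regions: Sequence[str] | None = None,
) -> ElectrodeGrid:
    """Construct an :class:`ElectrodeGrid`.

    Parameters
    ----------
    active_mask : array-like of bool or None
        ``None`` means all lattice sites carry an electrode.
    regions : sequence of str, optional
        Region tag per active electrode (row-major over active sites).
    """
    if active_mask is None:
        active_mask = np.ones((n_rows, n_cols), dtype=bool)
    return ElectrodeGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        spacing_mm=float(spacing_mm),
        active_mask=np.asarray(active_mask, dtype=bool),
        regions=tuple(regions) if regions is not None else (),
    )


def default_mapping_grid(region: str = "") -> ElectrodeGrid:
    """The default 249-electrode fixture: a 16x16 lattice with 7 masked sites.

    The physical arrangement of the mapping array is configurable; this
    default preserves the 249-electrode count and 2.5 mm spacing by
    masking seven sites nearest the four lattice corners (corner sites
    plus three second-ring corner sites).
    """
    mask = np.ones((16, 16), dtype=bool)
    for r, c in [(0, 0), (0, 15), (15, 0), (15, 15), (0, 1), (1, 0), (1, 15)]:
        mask[r, c] = False
    regions = [region] * int(mask.sum()) if region else None
    return build_grid(16, 16, 2.5, mask, regions)


@dataclass
class ActivationSeries:
    """Per-electrode sorted local activation times over a window.

    Parameters
    ----------
    times : mapping of int -> ndarray
        Activation times (ms) per active electrode; strictly
        increasing, separated by at least ``refractory_floor_ms``.
        Electrodes without activations may be absent.
    window_start_ms, window_end_ms : float
        Analysis window; all times fall inside it.
    refractory_floor_ms : float
        Minimal admissible interval between successive activations at
        one electrode.  Default 40 ms, shorter than any plausible
        atrial refractory period.
    """

    times: dict
    window_start_ms: float
    window_end_ms: float
    refractory_floor_ms: float = 40.0

    def __post_init__(self):
        if self.window_end_ms <= self.window_start_ms:
            raise ValueError("empty analysis window")
        clean = {}
        for e, t in self.times.items():
            t = np.atleast_1d(np.asarray(t, dtype=float))
            if t.size == 0:
                continue
            if np.any(~np.isfinite(t)):
                raise ValueError(f"non-finite activation time at electrode {e}")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"times at electrode {e} not strictly increasing")
            if t.size > 1 and np.any(np.diff(t) < self.refractory_floor_ms - 1e-9):
                raise ValueError(
                    f"interval below refractory floor at electrode {e}"
                )
            if t[0] < self.window_start_ms - 1e-9 or t[-1] > self.window_end_ms + 1e-9:
                raise ValueError(f"time outside window at electrode {e}")
            clean[int(e)] = t
        self.times = clean

    @property
    def window_ms(self) -> float:
        return self.window_end_ms - self.window_start_ms

    @property
    def n_events(self) -> int:
        return sum(t.size for t in self.times.values())

    def events(self) -> Iterator[tuple[int, float]]:
        """Iterate ``(electrode, at_ms)`` over all activation events."""
        for e in sorted(self.times):
            for t in self.times[e]:
                yield e, float(t)

    def event_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """All events as ``(electrodes, times)`` arrays (electrode-major)."""
        if not self.times:
            return np.empty(0, dtype=int), np.empty(0, dtype=float)
        es = np.concatenate(
            [np.full(self.times[e].size, e, dtype=int) for e in sorted(self.times)]
        )
        ts = np.concatenate([self.times[e] for e in sorted(self.times)])
        return es, ts


@dataclass
class EgmRecording:
    """Multichannel unipolar electrogram recording.

    ``signals`` is channels x samples in mV.  ``channel_map`` gives the
    electrode id of each channel; a ventricular reference channel, if
    present, is indicated by ``reference_channel`` and carries no
    electrode id (``-1`` in the map).
    """

    signals: np.ndarray
    sampling_rate_hz: float = 1039.0
    channel_map: np.ndarray = None
    reference_channel: int | None = None

    def __post_init__(self):
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("recording contains non-finite samples")
        if self.channel_map is None:
            cm = np.arange(self.signals.shape[0])
            if self.reference_channel is not None:
                cm[self.reference_channel] = -1
            self.channel_map = cm
        else:
            self.channel_map = np.asarray(self.channel_map, dtype=int)
        if self.channel_map.shape[0] != self.signals.shape[0]:
            raise ValueError("channel_map length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.sampling_rate_hz

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * 1000.0 / self.sampling_rate_hz

    def electrode_channels(self) -> np.ndarray:
        """Indices of channels mapped to electrodes (reference excluded)."""
        return np.nonzero(self.channel_map >= 0)[0]

    def validate_against(self, grid: ElectrodeGrid) -> None:
        n_el = (self.channel_map >= 0).sum()
        if n_el != grid.n_active:
            raise ValueError(
                f"{n_el} electrode channels but grid has {grid.n_active} electrodes"
            )


# ---------------------------------------------------------------------------
# file formats


def save_grid(grid: ElectrodeGrid, path) -> None:
    """Write a grid as JSON {n_rows, n_cols, spacing_mm, mask, regions}."""
    payload = {
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "spacing_mm": grid.spacing_mm,
        "mask": grid.active_mask.astype(int).tolist(),
        "regions": list(grid.regions),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_grid(path) -> ElectrodeGrid:
    payload = json.loads(Path(path).read_text())
    return build_grid(
        payload["n_rows"],
        payload["n_cols"],
        payload["spacing_mm"],
        np.asarray(payload["mask"], dtype=bool),
        payload.get("regions") or None,
    )


_AT_COLUMNS = ["electrode_id", "row", "col", "x_mm", "y_mm", "region", "at_ms"]


def save_activation_map(series: ActivationSeries, grid: ElectrodeGrid, path) -> None:
    """Write an activation map as tidy CSV (one row per activation event)."""
    rows = []
    for e, t in series.events():
        r, c = grid.electrode_rc[e]
        x, y = grid.coordinates[e]
        rows.append((e, int(r), int(c), x, y, grid.region_of(e), round(t, 3)))
    df = pd.DataFrame(rows, columns=_AT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.3f")


def load_activation_map(
    path,
    grid: ElectrodeGrid,
    window_ms: tuple[float, float] | None = None,
    refractory_floor_ms: float = 40.0,
) -> ActivationSeries:
    """Read a tidy activation-map CSV back into an :class:`ActivationSeries`.

    Electrode ids must exist on ``grid``; per-electrode times must be
    strictly increasing after sorting.  ``window_ms`` defaults to the
    observed time span.
    """
    df = pd.read_csv(path)
    missing = set(_AT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"activation map missing columns: {sorted(missing)}")
    ids = df["electrode_id"].to_numpy(dtype=int)
    if len(ids) and (ids.min() < 0 or ids.max() >= grid.n_active):
        raise ValueError("activation map references unknown electrode ids")
    times: dict[int, list] = {}
    for e, t in zip(ids, df["at_ms"].to_numpy(dtype=float)):
        times.setdefault(int(e), []).append(t)
    times = {e: np.sort(np.asarray(t)) for e, t in times.items()}
    if window_ms is None:
        if not times:
            raise ValueError("empty activation map needs an explicit window")
        lo = min(t[0] for t in times.values())
        hi = max(t[-1] for t in times.values())
        window_ms = (lo, hi + 1e-6)
    return ActivationSeries(
        times, window_ms[0], window_ms[1], refractory_floor_ms=refractory_floor_ms
    )


def save_recording(rec: EgmRecording, path_prefix) -> None:
    """Write a recording as ``<prefix>.npy`` plus ``<prefix>.json`` sidecar."""
    prefix = Path(path_prefix)
    np.save(prefix.with_suffix(".npy"), rec.signals)
    sidecar = {
        "sampling_rate_hz": rec.sampling_rate_hz,
        "channel_map": rec.channel_map.tolist(),
        "reference_channel": rec.reference_channel,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def load_recording(path_prefix) -> EgmRecording:
    prefix = Path(path_prefix)
    sidecar_path = prefix.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if "sampling_rate_hz" not in sidecar:
        raise ValueError("sidecar lacks sampling_rate_hz")
    signals = np.load(prefix.with_suffix(".npy"))
    return EgmRecording(
        signals=signals,
        sampling_rate_hz=sidecar["sampling_rate_hz"],
        channel_map=np.asarray(sidecar["channel_map"], dtype=int),
        reference_channel=sidecar.get("reference_channel"),
    )
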