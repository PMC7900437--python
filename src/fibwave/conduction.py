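"""Neighbor-link conduction analysis on activation-time maps.

Conduction block between adjacent electrodes is declared when the
apparent velocity over the inter-electrode distance falls below a
threshold (default 20 cm/s).  At 2.5 mm spacing this yields the
whole-millisecond activation-time-difference limits of 12 ms for
orthogonal and 17 ms for oblique neighbor pairs; links within the
limit are "conducted", links beyond it "blocked", and block lines
delineate fibrillation-wave boundaries.

Local conduction velocity is estimated at each activation event by
least-squares plane fitting of activation time over the event and its
conducted neighbors: with ``T(x, y) = a x + b y + c`` (ms, mm), speed
is ``100 / sqrt(a^2 + b^2)`` cm/s and the propagation direction is
``atan2(b, a)``.  Direction statistics use the circular mean resultant
length; dissociation is the blocked fraction of paired links.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .grid_io import OBLIQUE, ORTHOGONAL, ActivationSeries, ElectrodeGrid

__all__ = [
    "NeighborLinkSample",
    "CvEstimate",
    "BLOCK_VELOCITY_CM_S",
    "max_at_difference",
    "block_limits",
    "pair_neighbor_activations",
    "classify_links",
    "fit_local_cv",
    "fit_cv_map",
    "anisotropy_index",
    "mean_resultant_length",
    "dissociation_index",
    "afcl",
    "wavelength",
]

#: default apparent-velocity threshold below which a link is blocked
BLOCK_VELOCITY_CM_S = 20.0

CONDUCTED = "conducted"
BLOCKED = "blocked"
UNPAIRED = "unpaired"
PAIRED = "paired"


@dataclass(frozen=True)
class NeighborLinkSample:
    """One paired (or unpaired) activation comparison on a neighbor link."""

    electrode_a: int
    electrode_b: int
    relation: str
    t_a_ms: float
    t_b_ms: float | None
    delta_t_ms: float | None
    status: str = PAIRED


@dataclass(frozen=True)
class CvEstimate:
    """Local plane-fit conduction velocity at one activation event."""

    electrode: int
    at_ms: float
    speed_cm_s: float
    direction_rad: float
    n_neighbors_used: int
    rms_residual_ms: float
    valid: bool


def max_at_difference(
    spacing_mm: float,
    v_block_cm_s: float = BLOCK_VELOCITY_CM_S,
    relation: str = ORTHOGONAL,
) -> int:
    """Largest whole-ms neighbor delay still at/above the block velocity.

    The limit is ``floor(d / v)`` with the inter-electrode distance
    ``d`` (``spacing_mm`` orthogonally, ``spacing_mm * sqrt(2)``
    obliquely) and ``v`` in mm/ms: any longer integer delay implies an
    apparent velocity below ``v_block_cm_s``.  With 2.5 mm spacing and
    20 cm/s this gives the standard 12 ms / 17 ms limits.
    """
    if spacing_mm <= 0 or v_block_cm_s <= 0:
        raise ValueError("spacing and block velocity must be positive")
    distance = spacing_mm * (math.sqrt(2.0) if relation == OBLIQUE else 1.0)
    if relation not in (ORTHOGONAL, OBLIQUE):
        raise ValueError(f"unknown relation {relation!r}")
    v_mm_ms = v_block_cm_s / 100.0
    return int(math.floor(distance / v_mm_ms + 1e-9))


def block_limits(
    grid_or_spacing, v_block_cm_s: float = BLOCK_VELOCITY_CM_S
) -> dict[str, int]:
    """Per-relation AT-difference limits (ms) for a grid or spacing."""
    spacing = (
        grid_or_spacing.spacing_mm
        if isinstance(grid_or_spacing, ElectrodeGrid)
        else float(grid_or_spacing)
    )
    return {
        ORTHOGONAL: max_at_difference(spacing, v_block_cm_s, ORTHOGONAL),
        OBLIQUE: max_at_difference(spacing, v_block_cm_s, OBLIQUE),
    }


def _estimate_cycle_length(series: ActivationSeries) -> float:
    intervals = [
        np.diff(t) for t in series.times.values() if t.size >= 2
    ]
    if not intervals:
        return series.window_ms
    return float(np.median(np.concatenate(intervals)))


def pair_neighbor_activations(
    series: ActivationSeries,
    grid: ElectrodeGrid,
    pairing_window_ms: float | None = None,
) -> list[NeighborLinkSample]:
    """Mutual-nearest pairing of activations on every neighbor link.

    For each unordered neighbor pair, an activation at one electrode
    is paired with its nearest-in-time activation at the other when the
    two are mutually nearest and within ``pairing_window_ms`` (default
    half the running cycle-length estimate, to avoid cross-cycle
    pairing).  Activations without a counterpart yield ``unpaired``
    samples.
    """
    if series.n_events == 0:
        raise ValueError("empty activation series")
    if pairing_window_ms is None:
        pairing_window_ms = 0.5 * _estimate_cycle_length(series)
    out: list[NeighborLinkSample] = []
    for a, b, rel in grid.neighbor_pairs:
        ta = series.times.get(a)
        tb = series.times.get(b)
        if ta is None or tb is None:
            for e, tt in ((a, ta), (b, tb)):
                if tt is not None:
                    for t in tt:
                        out.append(
                            NeighborLinkSample(a, b, rel, float(t), None, None, UNPAIRED)
                        )
            continue
        # nearest counterpart of each a-event among b-events and vice versa
        ia = np.clip(np.searchsorted(tb, ta), 1, tb.size)
        near_a = np.where(
            np.abs(tb[ia - 1] - ta) <= np.abs(tb[np.minimum(ia, tb.size - 1)] - ta),
            ia - 1,
            np.minimum(ia, tb.size - 1),
        )
        ib = np.clip(np.searchsorted(ta, tb), 1, ta.size)
        near_b = np.where(
            np.abs(ta[ib - 1] - tb) <= np.abs(ta[np.minimum(ib, ta.size - 1)] - tb),
            ib - 1,
            np.minimum(ib, ta.size - 1),
        )
        paired_a = np.zeros(ta.size, dtype=bool)
        paired_b = np.zeros(tb.size, dtype=bool)
        for k in range(ta.size):
            m = near_a[k]
            if near_b[m] == k and abs(tb[m] - ta[k]) <= pairing_window_ms:
                out.append(
                    NeighborLinkSample(
                        a, b, rel, float(ta[k]), float(tb[m]),
                        float(tb[m] - ta[k]), PAIRED,
                    )
                )
                paired_a[k] = True
                paired_b[m] = True
        for t in ta[~paired_a]:
            out.append(NeighborLinkSample(a, b, rel, float(t), None, None, UNPAIRED))
        for t in tb[~paired_b]:
            out.append(NeighborLinkSample(b, a, rel, float(t), None, None, UNPAIRED))
    return out


def classify_links(
    links: Iterable[NeighborLinkSample], limits: Mapping[str, int]
) -> list[NeighborLinkSample]:
    """Set each paired link's status to conducted/blocked by the limits."""
    out = []
    for link in links:
        if link.delta_t_ms is None:
            out.append(replace(link, status=UNPAIRED))
        else:
            limit = limits[link.relation]
            status = CONDUCTED if abs(link.delta_t_ms) <= limit + 1e-9 else BLOCKED
            out.append(replace(link, status=status))
    return out


def fit_local_cv(
    series: ActivationSeries,
    grid: ElectrodeGrid,
    event: tuple[int, float],
    limits: Mapping[str, int] | None = None,
    min_neighbors: int = 3,
    min_gradient_ms_mm: float = 1e-6,
) -> CvEstimate:
    """Plane-fit local conduction velocity at one activation event.

    Fits ``T(x, y) = a x + b y + c`` over the event itself and the
    nearest-in-time activation of each direct neighbor within that
    relation's block limit (conducted neighbors only).  Invalid when
    fewer than ``min_neighbors`` conducted neighbors contribute, the
    gradient magnitude is below tolerance, or the neighbor geometry is
    degenerate.
    """
    if limits is None:
        limits = block_limits(grid)
    electrode, at = int(event[0]), float(event[1])
    te = series.times.get(electrode)
    if te is None or not np.any(np.isclose(te, at, atol=1e-6)):
        raise ValueError(f"event ({electrode}, {at}) not in series")
    xs, ys, ts = [grid.coordinates[electrode][0]], [grid.coordinates[electrode][1]], [at]
    n_used = 0
    for j, rel in grid.neighbors_of(electrode):
        tj = series.times.get(j)
        if tj is None:
            continue
        k = np.argmin(np.abs(tj - at))
        if abs(tj[k] - at) <= limits[rel] + 1e-9:
            xs.append(grid.coordinates[j][0])
            ys.append(grid.coordinates[j][1])
            ts.append(float(tj[k]))
            n_used += 1
    invalid = CvEstimate(electrode, at, float("nan"), float("nan"), n_used, float("nan"), False)
    if n_used < min_neighbors:
        return invalid
    A = np.column_stack([xs, ys, np.ones(len(xs))])
    if np.linalg.matrix_rank(A) < 3:
        return invalid
    coef, *_ = np.linalg.lstsq(A, np.asarray(ts), rcond=None)
    a, b, _c = coef
    grad = math.hypot(a, b)
    if grad < min_gradient_ms_mm:
        return invalid
    resid = A @ coef - np.asarray(ts)
    return CvEstimate(
        electrode=electrode,
        at_ms=at,
        speed_cm_s=100.0 / grad,
        direction_rad=math.atan2(b, a),
        n_neighbors_used=n_used,
        rms_residual_ms=float(np.sqrt(np.mean(resid**2))),
        valid=True,
    )


def fit_cv_map(
    series: ActivationSeries,
    grid: ElectrodeGrid,
    limits: Mapping[str, int] | None = None,
    **kwargs,
) -> list[CvEstimate]:
    """Plane-fit CV at every activation event of the series."""
    if limits is None:
        limits = block_limits(grid)
    return [
        fit_local_cv(series, grid, (e, t), limits, **kwargs)
        for e, t in series.events()
    ]


def mean_resultant_length(directions_rad: Sequence[float]) -> float:
    """``R-bar``, the magnitude of the mean unit direction vector."""
    z = np.exp(1j * np.asarray(directions_rad, dtype=float))
    return float(np.abs(z.mean()))


def anisotropy_index(
    cv_estimates: Iterable[CvEstimate], min_estimates: int = 3
) -> dict[int, float]:
    """Per-electrode anisotropy of conduction direction.

    The index is the mean resultant length ``R-bar`` of the electrode's
    valid conduction-direction vectors (1 = fixed preferential
    direction, 0 = isotropic; the circular variance is ``1 - R-bar``).
    Electrodes with fewer than ``min_estimates`` valid estimates are
    excluded.
    """
    by_electrode: dict[int, list[float]] = {}
    for est in cv_estimates:
        if est.valid:
            by_electrode.setdefault(est.electrode, []).append(est.direction_rad)
    return {
        e: mean_resultant_length(dirs)
        for e, dirs in sorted(by_electrode.items())
        if len(dirs) >= min_estimates
    }


def dissociation_index(links: Iterable[NeighborLinkSample]) -> float:
    """Percent of paired neighbor links classified as blocked."""
    n_paired = n_blocked = 0
    for link in links:
        if link.status in (CONDUCTED, BLOCKED):
            n_paired += 1
            n_blocked += link.status == BLOCKED
    if n_paired == 0:
        raise ValueError("dissociation undefined: no paired, classified links")
    return 100.0 * n_blocked / n_paired


def afcl(
    series: ActivationSeries,
    electrodes: Sequence[int] | None = None,
    min_activations: int = 3,
) -> tuple[dict[int, float], float]:
    """AF cycle length: per-electrode and regional medians (ms).

    Per electrode, the median of successive inter-activation intervals;
    electrodes with fewer than ``min_activations`` activations do not
    contribute.  The regional value is the median of electrode values.
    """
    if electrodes is None:
        electrodes = sorted(series.times)
    per_electrode = {}
    for e in electrodes:
        t = series.times.get(e)
        if t is not None and t.size >= min_activations:
            per_electrode[e] = float(np.median(np.diff(t)))
    if not per_electrode:
        raise ValueError(
            f"AFCL undefined: no electrode has >= {min_activations} activations"
        )
    return per_electrode, float(np.median(list(per_electrode.values())))


def wavelength(erp_ms: float, cv_cm_s: float) -> float:
    """Wavelength WL = ERP x CV, in mm (ms times cm/s / 100)."""
    if erp_ms <= 0 or cv_cm_s <= 0:
        raise ValueError("ERP and CV must be positive")
    return erp_ms * cv_cm_s / 100.0
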