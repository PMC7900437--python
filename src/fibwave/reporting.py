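"""ECG interval metrics, pharmacokinetic helper and summary tables.

ECG intervals (RR, QRS, QT, heart rate) are measured over a run of
consecutive beats — by default 10 RR intervals — with Q onset and S
offset located by amplitude-threshold crossings around the R peak and
the T-wave end by the tangent method (steepest descending tangent of
the T wave extrapolated to the isoelectric baseline).  QT is corrected
for heart rate with a configurable continuous piecewise-linear model;
the shipped default is an identity placeholder, since correction
coefficients are species- and study-specific.

Summary tables report median and IQR per region and timepoint
(linear-interpolation quantiles); groups with fewer than four
observations are flagged and excluded from comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import conduction, waves as waves_mod
from .grid_io import ActivationSeries, ElectrodeGrid

__all__ = [
    "EcgIntervals",
    "ecg_intervals",
    "PiecewiseQtcModel",
    "qtc_piecewise",
    "pk_free_concentration",
    "summarize_regions",
    "analyze_activation_series",
]


@dataclass(frozen=True)
class EcgIntervals:
    """Median ECG intervals over ``n_beats`` consecutive RR intervals."""

    rr_ms: float
    qrs_ms: float
    qt_ms: float
    qtc_ms: float
    heart_rate_bpm: float
    n_beats: int
    n_excluded: int = 0

    def __post_init__(self):
        if min(self.rr_ms, self.qrs_ms, self.qt_ms, self.heart_rate_bpm) <= 0:
            raise ValueError("ECG intervals must be positive")
        if self.qt_ms >= self.rr_ms:
            raise ValueError("QT must be shorter than RR")


def _detect_r_peaks(x: np.ndarray, fs: float, refractory_ms: float = 300.0):
    from scipy.signal import find_peaks

    mag = x - np.median(x)
    peak = np.abs(mag).max()
    if peak <= 0:
        raise ValueError("flat ECG channel")
    if np.abs(mag.min()) > np.abs(mag.max()):
        mag = -mag
    distance = max(1, int(math.ceil(refractory_ms * fs / 1000.0)))
    idx, _ = find_peaks(mag, height=0.5 * np.abs(mag).max(), distance=distance)
    return idx


def _beat_fiducials(x, fs, r_idx, rr_samples, qrs_threshold=0.05):
    """(q_onset, s_offset, t_end) sample positions for one beat, or None."""
    n = x.size
    base_lo = max(0, r_idx - int(0.30 * rr_samples))
    base_hi = max(base_lo + 1, r_idx - int(0.15 * rr_samples))
    baseline = float(np.median(x[base_lo:base_hi]))
    amp = x[r_idx] - baseline
    if amp == 0:
        return None
    thr = abs(amp) * qrs_threshold
    # Q onset: walk left from R until below threshold
    i = r_idx
    lim = max(0, r_idx - int(0.2 * fs))
    while i > lim and abs(x[i] - baseline) > thr:
        i -= 1
    q_on = i
    # S offset: walk right
    i = r_idx
    lim = min(n - 1, r_idx + int(0.2 * fs))
    while i < lim and abs(x[i] - baseline) > thr:
        i += 1
    s_off = i
    # T wave: dominant excursion between S offset and 70% of RR
    t_lo = s_off + int(0.04 * fs)
    t_hi = min(n - 1, r_idx + int(0.7 * rr_samples))
    if t_hi <= t_lo + 3:
        return None
    seg = x[t_lo:t_hi] - baseline
    t_peak = t_lo + int(np.argmax(np.abs(seg)))
    if abs(x[t_peak] - baseline) < 2 * thr:
        return None  # undetectable T wave
    # tangent method: steepest post-peak slope, extrapolated to baseline
    d_hi = min(n - 1, t_peak + int(0.25 * fs))
    d = np.diff(x[t_peak:d_hi])
    if d.size == 0:
        return None
    sign = 1.0 if x[t_peak] > baseline else -1.0
    k = int(np.argmin(sign * d))
    slope = d[k]  # per sample
    if sign * slope >= 0:
        return None
    m = t_peak + k
    t_end = m + (baseline - x[m]) / slope
    return q_on, s_off, t_end


def ecg_intervals(
    ecg: np.ndarray,
    fs_hz: float,
    n_beats: int = 10,
    qtc_model: "PiecewiseQtcModel | None" = None,
) -> EcgIntervals:
    """Measure HR, QRS and (rate-corrected) QT over consecutive beats.

    Needs at least ``n_beats + 1`` detectable beats.  Beats with an
    undetectable T wave are excluded and counted.  The heart rate is
    ``60000 / median RR``; QTc applies ``qtc_model`` (identity
    placeholder by default).
    """
    x = np.asarray(ecg, dtype=float)
    r_idx = _detect_r_peaks(x, fs_hz)
    if r_idx.size < n_beats + 1:
        raise ValueError(
            f"need >= {n_beats + 1} beats, found {r_idx.size}"
        )
    r_idx = r_idx[: n_beats + 1]
    rr = np.diff(r_idx) * 1000.0 / fs_hz
    rr_samples = int(np.median(np.diff(r_idx)))
    qrs_list, qt_list, excluded = [], [], 0
    for r in r_idx[:n_beats]:
        fid = _beat_fiducials(x, fs_hz, int(r), rr_samples)
        if fid is None:
            excluded += 1
            continue
        q_on, s_off, t_end = fid
        qrs_list.append((s_off - q_on) * 1000.0 / fs_hz)
        qt_list.append((t_end - q_on) * 1000.0 / fs_hz)
    if not qt_list:
        raise ValueError("no beat with a measurable T wave")
    rr_med = float(np.median(rr))
    hr = 60000.0 / rr_med
    qt_med = float(np.median(qt_list))
    model = qtc_model if qtc_model is not None else PiecewiseQtcModel.identity()
    return EcgIntervals(
        rr_ms=rr_med,
        qrs_ms=float(np.median(qrs_list)),
        qt_ms=qt_med,
        qtc_ms=model(qt_med, hr),
        heart_rate_bpm=hr,
        n_beats=n_beats,
        n_excluded=excluded,
    )


@dataclass(frozen=True)
class PiecewiseQtcModel:
    """Continuous piecewise-linear heart-rate correction of QT.

    ``QTc = QT - (intercept_i + slope_i * HR)`` on the HR segment
    ``i`` delimited by ``breakpoints`` (bpm).  Segments must join
    continuously at every breakpoint.  Coefficients are configuration
    input; the shipped default is the identity placeholder (single
    segment, zero slope and intercept) because correction coefficients
    are population-specific and must be supplied by the user.
    """

    breakpoints: tuple
    slopes: tuple
    intercepts: tuple

    def __post_init__(self):
        if len(self.slopes) != len(self.breakpoints) + 1:
            raise ValueError("need one more segment than breakpoints")
        if len(self.intercepts) != len(self.slopes):
            raise ValueError("slopes and intercepts must align")
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        for i, b in enumerate(self.breakpoints):
            left = self.intercepts[i] + self.slopes[i] * b
            right = self.intercepts[i + 1] + self.slopes[i + 1] * b
            if abs(left - right) > 1e-6:
                raise ValueError(f"discontinuous model at breakpoint {b}")

    @classmethod
    def identity(cls) -> "PiecewiseQtcModel":
        return cls(breakpoints=(), slopes=(0.0,), intercepts=(0.0,))

    @classmethod
    def from_dict(cls, cfg: dict) -> "PiecewiseQtcModel":
        return cls(
            breakpoints=tuple(cfg.get("breakpoints", ())),
            slopes=tuple(cfg["slopes"]),
            intercepts=tuple(cfg["intercepts"]),
        )

    def correction(self, hr_bpm: float) -> float:
        i = int(np.searchsorted(np.asarray(self.breakpoints), hr_bpm, side="right"))
        return self.intercepts[i] + self.slopes[i] * hr_bpm

    def __call__(self, qt_ms: float, hr_bpm: float) -> float:
        return qt_ms - self.correction(hr_bpm)


def qtc_piecewise(
    qt_ms: float, hr_bpm: float, model: "PiecewiseQtcModel | dict"
) -> float:
    """Rate-corrected QT from a continuous piecewise-linear model."""
    if isinstance(model, dict):
        model = PiecewiseQtcModel.from_dict(model)
    return model(qt_ms, hr_bpm)


def pk_free_concentration(total_conc_um: float, protein_binding_pct: float) -> float:
    """Free (unbound) plasma concentration, to two significant figures.

    ``free = total * (100 - binding) / 100``; e.g. a total of 27.4 uM
    at 90.5% plasma protein binding leaves ~2.6 uM unbound.
    """
    if not 0.0 <= protein_binding_pct <= 100.0:
        raise ValueError("protein binding must be in [0, 100]%")
    free = total_conc_um * (100.0 - protein_binding_pct) / 100.0
    if free == 0.0:
        return 0.0
    return float(round(free, -int(math.floor(math.log10(abs(free)))) + 1))


def summarize_regions(
    table: pd.DataFrame,
    metrics: list | None = None,
    group_cols: tuple = ("region", "timepoint"),
    min_n: int = 4,
) -> pd.DataFrame:
    """Median-with-IQR summary per region x timepoint.

    Returns a tidy frame with one row per group and metric: ``n``,
    ``median``, ``q1``, ``q3``, ``iqr`` (linear-interpolation
    quantiles) and an ``included`` flag — groups with fewer than
    ``min_n`` non-missing observations are flagged and excluded from
    downstream comparison.  Row order of the input is irrelevant.
    """
    group_cols = [c for c in group_cols if c in table.columns]
    if not group_cols:
        raise ValueError("no grouping columns present")
    if metrics is None:
        metrics = [
            c for c in table.columns
            if c not in group_cols and pd.api.types.is_numeric_dtype(table[c])
            and c != "electrode"
        ]
    rows = []
    for key, grp in table.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        for m in metrics:
            vals = grp[m].dropna().to_numpy(dtype=float)
            n = vals.size
            if n == 0:
                rows.append((*key, m, 0, np.nan, np.nan, np.nan, np.nan, False))
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append((*key, m, n, med, q1, q3, q3 - q1, n >= min_n))
    return pd.DataFrame(
        rows, columns=[*group_cols, "metric", "n", "median", "q1", "q3", "iqr", "included"]
    )


def analyze_activation_series(
    series: ActivationSeries,
    grid: ElectrodeGrid,
    v_block_cm_s: float = conduction.BLOCK_VELOCITY_CM_S,
    min_wave_electrodes: int = 3,
) -> dict:
    """Full conduction/wave analysis of one activation map.

    Runs link pairing and block classification, plane-fit CV,
    anisotropy, dissociation, AFCL, wave reconstruction with origin
    classification and size filtering, cycle-normalized counts and
    re-entry detection.  Returns a dict with a per-electrode tidy
    table (``per_electrode``), the summary scalars (``summary``) and
    the intermediate objects.
    """
    limits = conduction.block_limits(grid, v_block_cm_s)
    links = conduction.classify_links(
        conduction.pair_neighbor_activations(series, grid), limits
    )
    afcl_per_electrode, afcl_regional = conduction.afcl(series)
    estimates = conduction.fit_cv_map(series, grid, limits)
    aniso = conduction.anisotropy_index(estimates)
    dissociation = conduction.dissociation_index(links)
    wave_list = waves_mod.filter_waves(
        waves_mod.reconstruct_waves(series, grid, limits), min_wave_electrodes
    )
    counts = waves_mod.normalize_counts(wave_list, series.window_ms, afcl_regional)
    reentries, reentry_summary = waves_mod.detect_reentries(
        wave_list, grid, limits, afcl_regional, window_ms=series.window_ms
    )
    speed_by_electrode: dict[int, list] = {}
    for est in estimates:
        if est.valid:
            speed_by_electrode.setdefault(est.electrode, []).append(est.speed_cm_s)
    rows = []
    for e in range(grid.n_active):
        speeds = speed_by_electrode.get(e)
        rows.append(
            {
                "electrode": e,
                "region": grid.region_of(e),
                "afcl_ms": afcl_per_electrode.get(e, np.nan),
                "cv_cm_s": float(np.median(speeds)) if speeds else np.nan,
                "anisotropy": aniso.get(e, np.nan),
            }
        )
    per_electrode = pd.DataFrame(rows)
    summary = {
        "afcl_ms": afcl_regional,
        "cv_cm_s": float(per_electrode["cv_cm_s"].median()),
        "anisotropy": float(per_electrode["anisotropy"].median()),
        "dissociation_pct": dissociation,
        **counts,
        **reentry_summary,
        "limits_ms": limits,
        "window_ms": series.window_ms,
    }
    return {
        "per_electrode": per_electrode,
        "summary": summary,
        "links": links,
        "cv_estimates": estimates,
        "waves": wave_list,
        "reentries": reentries,
    }
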