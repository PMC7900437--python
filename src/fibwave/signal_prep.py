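"""Ventricular far-field removal and activation-time detection.

Unipolar atrial electrograms contain, besides the local atrial
deflections, a ventricular far-field (QRST) component.  It is removed
by averaged-beat template cancellation: ventricular beats are located
on a dedicated reference channel, a per-channel template is formed by
averaging beat-aligned windows, and the template (optionally
least-squares amplitude-scaled per beat) is subtracted at every
fiducial.  Samples outside beat windows are never touched.

Local activation times are marked at the steepest negative slope of
the unipolar electrogram.  Candidates are local minima of the first
difference below an amplitude-invariant threshold (``k`` times the
MAD of the channel's derivative); non-maximum suppression within a
refractory period keeps the steeper candidate, and an optional
periodicity prior iteratively re-scores candidates against the
channel's running cycle-length estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grid_io import ActivationSeries, EgmRecording

__all__ = [
    "BeatList",
    "NoBeatsError",
    "detect_ventricular_beats",
    "cancel_qrst",
    "detect_activation_times",
    "match_activation_times",
]


class NoBeatsError(ValueError):
    """Raised when no ventricular beats can be located."""


@dataclass(frozen=True)
class BeatList:
    """Ventricular beat fiducial times (ms) from a reference channel."""

    times_ms: np.ndarray
    channel: int

    def __post_init__(self):
        t = np.asarray(self.times_ms, dtype=float)
        if t.size and np.any(np.diff(t) < 300.0 - 1e-9):
            raise ValueError("inter-beat interval below 300 ms")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("beat times not strictly increasing")
        object.__setattr__(self, "times_ms", t)

    @property
    def n_beats(self) -> int:
        return self.times_ms.size


def detect_ventricular_beats(
    rec: EgmRecording,
    ref_channel: int | None = None,
    refractory_ms: float = 300.0,
    min_rel_height: float = 0.4,
) -> BeatList:
    """Locate ventricular beats on the reference channel.

    Fiducials are placed at the dominant deflection (largest absolute
    excursion from the baseline median) of each beat, with a 300 ms
    refractory period.  Candidate peaks far below the median peak
    amplitude (T waves, atrial far-field) are rejected.  At least two
    beats are required for template cancellation.
    """
    from scipy.signal import find_peaks

    if ref_channel is None:
        ref_channel = rec.reference_channel
    if ref_channel is None:
        raise ValueError("recording has no ventricular reference channel")
    x = rec.signals[ref_channel]
    mag = np.abs(x - np.median(x))
    peak = mag.max()
    if peak <= 0:
        raise NoBeatsError("flat reference channel")
    distance = max(1, int(math.ceil(refractory_ms * rec.sampling_rate_hz / 1000.0)))
    idx, _ = find_peaks(mag, height=min_rel_height * peak, distance=distance)
    if idx.size:
        idx = idx[mag[idx] >= 0.6 * np.median(mag[idx])]
    if idx.size < 2:
        raise NoBeatsError(f"only {idx.size} beat(s) found; need >= 2")
    return BeatList(times_ms=idx * 1000.0 / rec.sampling_rate_hz, channel=ref_channel)


def cancel_qrst(
    rec: EgmRecording,
    beats: BeatList,
    window_ms: tuple[float, float] = (-100.0, 500.0),
    per_beat_scaling: bool = False,
) -> EgmRecording:
    """Averaged-beat QRST template cancellation.

    Per channel, beat-aligned windows around each fiducial form the
    averaged-beat template (only windows fully inside the recording
    contribute; with three or more complete beats the sample-wise
    median is used, which suppresses leakage of sparse, beat-asynchronous
    atrial deflections into the template).  The template — optionally
    with a per-beat least-squares amplitude scale — is subtracted at
    every fiducial.  Samples outside beat windows are returned
    unchanged; where consecutive beat windows overlap, the earlier
    beat takes precedence.
    """
    out = rec.signals.copy()
    if beats.n_beats == 0:
        return EgmRecording(out, rec.sampling_rate_hz, rec.channel_map.copy(),
                            rec.reference_channel)
    fs = rec.sampling_rate_hz
    lo_off = int(round(window_ms[0] * fs / 1000.0))
    hi_off = int(round(window_ms[1] * fs / 1000.0))
    width = hi_off - lo_off
    if width <= 0:
        raise ValueError("empty cancellation window")
    centers = np.round(beats.times_ms * fs / 1000.0).astype(int)
    full = [c for c in centers if c + lo_off >= 0 and c + hi_off <= rec.n_samples]
    if len(full) < 2:
        raise ValueError("need >= 2 complete beat windows for a template")
    stack = np.stack([rec.signals[:, c + lo_off : c + hi_off] for c in full])
    template = np.median(stack, axis=0) if len(full) >= 3 else stack.mean(axis=0)
    tnorm = np.einsum("cw,cw->c", template, template)

    claimed = np.zeros(rec.n_samples, dtype=bool)
    for c in centers:
        a = max(0, c + lo_off)
        b = min(rec.n_samples, c + hi_off)
        if b <= a:
            continue
        ta = a - (c + lo_off)
        seg = slice(a, b)
        free = ~claimed[seg]
        if not free.any():
            continue
        tmpl = template[:, ta : ta + (b - a)]
        if per_beat_scaling:
            with np.errstate(invalid="ignore", divide="ignore"):
                num = np.einsum("cw,cw->c", rec.signals[:, seg], tmpl)
                scale = np.where(tnorm > 0, num / np.where(tnorm > 0, tnorm, 1.0), 1.0)
        else:
            scale = np.ones(rec.n_channels)
        out[:, seg][:, free] -= scale[:, None] * tmpl[:, free]
        claimed[seg] |= True
    return EgmRecording(out, fs, rec.channel_map.copy(), rec.reference_channel)


def _candidate_minima(d: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of strict local minima of the derivative below threshold."""
    if d.size < 3:
        return np.empty(0, dtype=int)
    core = d[1:-1]
    is_min = (core < d[:-2]) & (core <= d[2:]) & (core < threshold)
    return np.nonzero(is_min)[0] + 1


def _nms(idx: np.ndarray, d: np.ndarray, refractory_samples: int) -> np.ndarray:
    """Keep the steeper candidate within each refractory neighborhood."""
    order = idx[np.argsort(d[idx], kind="stable")]  # steepest (most negative) first
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) >= refractory_samples for j in kept):
            kept.append(int(i))
    return np.sort(np.asarray(kept, dtype=int))


def detect_activation_times(
    rec: EgmRecording,
    deriv_threshold_k: float = 4.0,
    refractory_ms: float = 40.0,
    smooth_ms: float = 2.0,
    cycle_prior: bool = False,
    max_iter: int = 10,
    min_score_rel: float = 0.05,
) -> ActivationSeries:
    """Steepest-negative-slope activation-time detection.

    Candidates are local minima of the first difference below
    ``-k * 1.4826 * MAD`` of the channel's derivative; the derivative
    is smoothed with a centered moving average of ``smooth_ms``
    (matched to the deflection width) so that noise does not dominate
    the slope estimate.  Non-maximum suppression within
    ``refractory_ms`` keeps the steeper candidate.
    With ``cycle_prior`` a periodicity refinement iterates: estimate
    the per-channel cycle length, re-score candidates by slope
    magnitude times a Gaussian periodicity likelihood around the
    expected next activation, and drop low-scoring candidates, until a
    fixed point (at most ``max_iter`` iterations).  Constant channels
    yield no activations.  The recording should be far-field-free.
    """
    fs = rec.sampling_rate_hz
    refractory_samples = max(1, int(math.ceil(refractory_ms * fs / 1000.0)))
    times: dict[int, np.ndarray] = {}
    for ch in rec.electrode_channels():
        electrode = int(rec.channel_map[ch])
        x = rec.signals[ch]
        d = np.diff(x) * fs / 1000.0  # mV/ms
        win = int(round(smooth_ms * fs / 1000.0)) | 1  # odd length
        if win > 1 and d.size >= win:
            d = np.convolve(d, np.ones(win) / win, mode="same")
        mad = np.median(np.abs(d - np.median(d)))
        threshold = -deriv_threshold_k * 1.4826 * mad - 1e-9
        cand = _candidate_minima(d, threshold)
        if cand.size == 0:
            continue
        kept = _nms(cand, d, refractory_samples)
        if cycle_prior and kept.size >= 3:
            kept = _refine_with_cycle_prior(
                cand, kept, d, fs, refractory_samples, max_iter, min_score_rel
            )
        if kept.size:
            # sub-sample refinement: parabolic interpolation of the
            # derivative minimum (removes sample-grid staircase bias
            # from downstream plane fits)
            frac = np.zeros(kept.size)
            inner = (kept > 0) & (kept < d.size - 1)
            km = kept[inner]
            denom = d[km - 1] - 2 * d[km] + d[km + 1]
            ok = denom > 0
            frac[inner] = np.where(
                ok, 0.5 * (d[km - 1] - d[km + 1]) / np.where(ok, denom, 1.0), 0.0
            )
            frac = np.clip(frac, -0.5, 0.5)
            times[electrode] = (kept + frac + 0.5) * 1000.0 / fs
    window_end = rec.duration_ms + 1e-6
    return ActivationSeries(
        times, 0.0, window_end, refractory_floor_ms=refractory_ms
    )


def _refine_with_cycle_prior(
    cand, kept, d, fs, refractory_samples, max_iter, min_score_rel
):
    prev = kept
    for _ in range(max_iter):
        if prev.size < 3:
            return prev
        cl = np.median(np.diff(prev))
        if cl <= 0:
            return prev
        sd = 0.2 * cl
        expected = np.sort(np.concatenate([prev - cl, prev, prev + cl]))
        gaps = np.abs(cand[:, None] - expected[None, :]).min(axis=1)
        score = np.abs(d[cand]) * np.exp(-(gaps**2) / (2 * sd**2))
        good = cand[score >= min_score_rel * score.max()]
        new = _nms(good, d, refractory_samples)
        if new.size == prev.size and np.array_equal(new, prev):
            return new
        prev = new
    return prev


def match_activation_times(
    truth: ActivationSeries,
    detected: ActivationSeries,
    tolerance_ms: float = 5.0,
) -> dict:
    """Sensitivity/precision of detected activations against ground truth.

    Per electrode, detected and true events are matched greedily in
    time order; a detection within ``tolerance_ms`` of an unmatched
    true event counts as a hit.
    """
    n_true = n_det = n_hit = 0
    electrodes = set(truth.times) | set(detected.times)
    for e in electrodes:
        tt = truth.times.get(e, np.empty(0))
        td = detected.times.get(e, np.empty(0))
        n_true += tt.size
        n_det += td.size
        used = np.zeros(tt.size, dtype=bool)
        for t in td:
            if tt.size == 0:
                continue
            k = int(np.argmin(np.where(used, np.inf, np.abs(tt - t))))
            if not used[k] and abs(tt[k] - t) <= tolerance_ms:
                used[k] = True
                n_hit += 1
    return {
        "n_true": n_true,
        "n_detected": n_det,
        "n_matched": n_hit,
        "sensitivity": n_hit / n_true if n_true else float("nan"),
        "precision": n_hit / n_det if n_det else float("nan"),
    }
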