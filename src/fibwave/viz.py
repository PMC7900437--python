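"""Isochronal activation-map rendering."""

from __future__ import annotations

import numpy as np

from .grid_io import ActivationSeries, ElectrodeGrid


def plot_isochrones(
    series: ActivationSeries,
    grid: ElectrodeGrid,
    t_start_ms: float | None = None,
    t_end_ms: float | None = None,
    ax=None,
    cmap: str = "viridis",
):
    """Color map of the first activation per electrode within a window.

    Electrodes without an activation in the window are left blank.
    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if t_start_ms is None:
        t_start_ms = series.window_start_ms
    if t_end_ms is None:
        t_end_ms = series.window_end_ms
    img = np.full((grid.n_rows, grid.n_cols), np.nan)
    for e, t in series.times.items():
        in_win = t[(t >= t_start_ms) & (t < t_end_ms)]
        if in_win.size:
            r, c = grid.electrode_rc[e]
            img[r, c] = in_win[0] - t_start_ms
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    m = ax.imshow(img, origin="lower", cmap=cmap, interpolation="nearest")
    ax.figure.colorbar(m, ax=ax, label="activation time (ms)")
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    ax.set_title(f"isochrones {t_start_ms:.0f}-{t_end_ms:.0f} ms")
    return ax
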