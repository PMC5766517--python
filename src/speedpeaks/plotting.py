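"""Raster figure for s-Peak matrices (rows = cycles, touch marker, column
histogram, mean speed overlay)."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .fluctuations import SPeakMatrix, SPeakTrain
from .preprocess import SpeedSeries


def plot_raster(
    matrix: SPeakMatrix,
    train: SPeakTrain | None = None,
    speed: SpeedSeries | None = None,
    path: str | None = None,
):
    """Render the cycles-by-frames raster with its per-column count panel.

    When ``train`` and ``speed`` are given, overlays the across-cycle mean
    speed profile on the raster panel.
    """
    m = matrix.matrix
    fig, (ax_raster, ax_hist) = plt.subplots(
        2, 1, sharex=True, figsize=(8, 6), height_ratios=[3, 1]
    )
    rows, cols = np.nonzero(m)
    ax_raster.scatter(cols, rows, s=2, c="tab:green", marker="|")
    if matrix.touch_column is not None:
        ax_raster.axvline(matrix.touch_column, color="gold", lw=1.5, label="touch")
        ax_raster.legend(loc="upper right", fontsize=8)
    ax_raster.set_ylabel("cycle index")
    ax_raster.invert_yaxis()

    if train is not None and speed is not None and matrix.touch_column is not None:
        half = matrix.touch_column
        profiles = []
        for (s, e), t in zip(train.bounds, train.touches or ()):
            lo, hi = t - half, t + half
            seg = np.full(2 * half, np.nan)
            src_lo, src_hi = max(lo, 0), min(hi, speed.n_frames)
            seg[src_lo - lo : src_hi - lo] = speed.speed[src_lo:src_hi]
            profiles.append(seg)
        mean_speed = np.nanmean(np.vstack(profiles), axis=0)
        ax2 = ax_raster.twinx()
        ax2.plot(mean_speed, color="m", lw=1, alpha=0.8)
        ax2.set_ylabel("mean speed (m/s)", color="m")

    ax_hist.bar(np.arange(m.shape[1]), matrix.column_counts, width=1, color="k")
    ax_hist.set_xlabel("frame (cycle-aligned)")
    ax_hist.set_ylabel("s-Peak count")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
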