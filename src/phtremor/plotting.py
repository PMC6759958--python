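"""Figure helpers for the main pipeline outputs (matplotlib)."""
from __future__ import annotations

import numpy as np

__all__ = [
    "plot_heart_rate_and_artifact",
    "plot_tremor_timecourse",
    "plot_connectivity_delta",
]


def _get_axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_heart_rate_and_artifact(hr_times, hr_bpm, bold=None, mask=None, ax=None):
    """Heart-rate trace with (optionally) the mean in-mask BOLD drift."""
    ax = _get_axes(ax)
    ax.plot(hr_times, hr_bpm, color="k", label="heart rate (bpm)")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("heart rate (bpm)")
    if bold is not None:
        sel = np.asarray(mask, bool) if mask is not None else \
            np.ones(bold.grid_shape, bool)
        trace = bold.data[sel].mean(axis=0)
        ax2 = ax.twinx()
        ax2.plot(bold.frame_times(), trace, color="tab:red",
                 label="mean BOLD")
        ax2.set_ylabel("mean BOLD signal")
    return ax


def plot_tremor_timecourse(results, ax=None):
    """Normalised 10-min tremor index vs time, injection marked."""
    ax = _get_axes(ax)
    w = results.windows
    ax.plot(w.bin_start_s / 60.0, w.index, marker="o")
    ax.axvline(results.injection_s / 60.0, color="r", linestyle="--",
               label="injection")
    ax.axhline(1.0, color="gray", linewidth=0.5)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("normalised tremor index")
    ax.legend()
    return ax


def plot_connectivity_delta(delta, significant=None, ax=None, vmax=None):
    """Heatmap of a connectivity-change matrix with significance dots."""
    ax = _get_axes(ax)
    mat = delta.to_numpy() if hasattr(delta, "to_numpy") else np.asarray(delta)
    names = list(delta.index) if hasattr(delta, "index") else \
        [str(i) for i in range(mat.shape[0])]
    v = vmax or np.nanmax(np.abs(mat[~np.eye(len(names), dtype=bool)])) or 1.0
    im = ax.imshow(mat, cmap="RdBu_r", vmin=-v, vmax=v)
    ax.set_xticks(range(len(names)), names, rotation=45, ha="right")
    ax.set_yticks(range(len(names)), names)
    if significant is not None:
        sig = significant.to_numpy() if hasattr(significant, "to_numpy") else \
            np.asarray(significant)
        ys, xs = np.nonzero(sig)
        ax.scatter(xs, ys, s=12, c="k", marker=".")
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax
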