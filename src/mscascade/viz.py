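"""Plotting helpers: scalp topographies and attention overlays."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .montage import Montage, standard_1020_19

__all__ = ["plot_topography", "plot_attention_overlay"]


def plot_topography(topo: np.ndarray, montage: Montage | None = None, path: str | Path | None = None, title: str = ""):
    """Render one channel map as an interpolated scalp view (2D projection)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.interpolate import griddata

    montage = montage or standard_1020_19()
    xy = montage.positions
    grid = np.linspace(-1.1, 1.1, 80)
    gx, gy = np.meshgrid(grid, grid)
    gz = griddata(xy, topo, (gx, gy), method="cubic")
    mask = gx**2 + gy**2 > 1.1**2
    gz = np.where(mask, np.nan, gz)

    fig, ax = plt.subplots(figsize=(3, 3))
    lim = np.nanmax(np.abs(gz)) or 1.0
    ax.contourf(gx, gy, gz, levels=21, cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.scatter(xy[:, 0], xy[:, 1], s=6, c="k")
    ax.add_patch(plt.Circle((0, 0), 1.05, fill=False, lw=1.2))
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_attention_overlay(fused_values: np.ndarray, attention_upsampled: np.ndarray, path: str | Path | None = None, title: str = ""):
    """Fused soft-sequence heatmap with the temporal attention curve on top."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(8, 3.2), sharex=True, height_ratios=[1, 2], constrained_layout=True
    )
    t = np.arange(attention_upsampled.size)
    ax0.plot(t, attention_upsampled, lw=0.8, color="crimson")
    ax0.set_ylabel("attention")
    ax0.set_title(title)
    ax1.imshow(fused_values, aspect="auto", origin="upper", cmap="viridis", interpolation="nearest")
    ax1.set_yticks(range(fused_values.shape[0]))
    ax1.set_ylabel("fused rows")
    ax1.set_xlabel("sample")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
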