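"""Basic inspection plots: orthogonal-slice difference overlays and
trajectory panels. These are working views, not publication figures."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .longitudinal import DifferenceMap, VolumeTrajectory


def plot_difference_orthoslices(dm: DifferenceMap, background: np.ndarray | None = None):
    """Three orthogonal mid-slices of a signed difference map.

    Increases render red, decreases blue, on a symmetric scale; the
    earlier timepoint's anatomy (any scalar volume) can be underlaid.
    """
    vals = np.where(dm.matched_coverage, dm.values, np.nan)
    lim = np.nanmax(np.abs(vals)) if np.isfinite(vals).any() else 1.0
    centers = [s // 2 for s in vals.shape]
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.5))
    slicers = [
        (np.s_[centers[0], :, :], "sagittal"),
        (np.s_[:, centers[1], :], "coronal"),
        (np.s_[:, :, centers[2]], "axial"),
    ]
    for ax, (sl, name) in zip(axes, slicers):
        if background is not None:
            ax.imshow(background[sl].T, cmap="gray", origin="lower")
        im = ax.imshow(vals[sl].T, cmap="RdBu_r", vmin=-lim, vmax=lim,
                       origin="lower", alpha=0.85)
        ax.set_title(f"{dm.metabolite} Δ ({name})", fontsize=9)
        ax.axis("off")
    fig.colorbar(im, ax=axes, shrink=0.8, label="later − earlier")
    fig.suptitle(f"{dm.pair[0]} → {dm.pair[1]}", fontsize=10)
    return fig


def plot_trajectories(trajectories: list[VolumeTrajectory], title: str = ""):
    """Raw volume (top) and percent change (bottom) per mask family."""
    fig, (ax_v, ax_p) = plt.subplots(2, 1, figsize=(6, 6), sharex=True)
    for traj in trajectories:
        months = traj.months
        vols = [v if v is not None else np.nan for v in traj.volume_cc]
        ax_v.plot(months, vols, marker="o", label=traj.mask_family)
        pct = [p if p is not None else np.nan for p in traj.percent_change]
        ax_p.plot(months[1:], pct, marker="s", label=traj.mask_family)
    ax_v.set_ylabel("volume (cc)")
    ax_p.set_ylabel("% change vs previous scan")
    ax_p.set_xlabel("months from RT")
    ax_p.axhline(0, color="k", lw=0.5)
    ax_v.legend(fontsize=8)
    if title:
        fig.suptitle(title)
    return fig
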