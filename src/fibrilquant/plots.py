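"""Optional matplotlib figures for the three standard readouts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .coverage import CoverageResult
from .glcm import GLCMDecay
from .orientation import OrientationHistogram

__all__ = ["plot_orientation_histogram", "plot_decay_curve", "plot_depth_profile"]


def plot_orientation_histogram(hist: OrientationHistogram, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(hist.bin_centers_deg, hist.frequency,
           width=np.diff(hist.bin_edges_deg), color="#3b6ea5")
    ax.axvline(hist.peak_angle_deg, color="crimson", lw=1,
               label=f"peak {hist.peak_angle_deg:.1f} deg")
    ax.set_xlabel("orientation (deg)")
    ax.set_ylabel("frequency")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_decay_curve(decay: GLCMDecay, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(decay.distances_px, decay.correlation, "o-", ms=3)
    ax.set_xlabel("offset distance (px)")
    ax.set_ylabel("GLCM correlation")
    ax.set_title(f"auc={decay.auc:.3f}, half-decay={decay.half_decay_distance_px:.1f} px",
                 fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_depth_profile(result: CoverageResult, path) -> None:
    if not result.by_depth:
        raise ValueError("coverage result carries no depth profile")
    depth, pct = zip(*result.by_depth)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(depth, pct, "o-")
    ax.axhline(result.peak_coverage_percent, ls="--", color="gray", lw=0.8)
    ax.set_xlabel("depth (um)")
    ax.set_ylabel("coverage (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
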