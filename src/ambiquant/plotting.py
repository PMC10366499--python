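"""Diagnostic plots: rank curve with knee, secant fan, slope histograms.

Plots are optional and never feed back into metric computation.
"""

from __future__ import annotations

import numpy as np

from .curve_metrics import SecantProfile
from .rankcurve import RankedCurve
from .slope_metrics import SlopeDistribution

__all__ = ["plot_rank_curve", "plot_secant_fan", "plot_slope_distribution"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_rank_curve(curve: RankedCurve, ax=None):
    """Normalized cumulative-count curve with the estimated-cell rank."""
    ax = _axes(ax)
    ax.plot(curve.x, curve.c, lw=1.5, label="cumulative counts")
    knee_x = curve.n_cells_est / curve.N
    ax.axvline(knee_x, color="tab:red", ls="--", lw=1, label=f"est. cells = {curve.n_cells_est}")
    ax.set_xlabel("normalized barcode rank")
    ax.set_ylabel("normalized cumulative UMI count")
    ax.legend(frameon=False)
    return ax


def plot_secant_fan(curve: RankedCurve, profile: SecantProfile, ax=None, n_secants: int = 25):
    """Curve, diagonal, secant fan, max secant and the minimal rectangle."""
    ax = _axes(ax)
    ax.plot(curve.x, curve.c, lw=1.5, color="tab:blue", label="cumulative counts")
    ax.plot([0, 1], [0, 1], color="grey", lw=1, label="diagonal")
    step = max(1, curve.N // n_secants)
    for i in range(0, curve.N, step):
        ax.plot([curve.x[i], curve.x[i]], [curve.x[i], curve.c[i]], color="0.8", lw=0.5)
    imax = int(np.argmax(profile.d))
    ax.plot(
        [curve.x[imax], curve.x[imax]],
        [curve.x[imax], curve.c[imax]],
        color="tab:red",
        lw=1.5,
        label=f"max secant = {profile.max_d:.3f}",
    )
    ax.plot([0, 1, 1, 0, 0], [0, 0, 1, 1, 0], color="k", lw=0.8, ls=":")
    ax.set_xlabel("normalized barcode rank")
    ax.set_ylabel("normalized cumulative UMI count")
    ax.legend(frameon=False)
    return ax


def plot_slope_distribution(dist: SlopeDistribution, ax=None, scaled: bool = True):
    """Scaled (midpoint-weighted) or raw slope histogram with threshold."""
    ax = _axes(ax)
    heights = dist.y if scaled else dist.frequencies
    width = (
        (dist.midpoints[1] - dist.midpoints[0]) if len(dist.midpoints) > 1 else dist.midpoints[0]
    )
    ax.bar(dist.midpoints, heights, width=width * 0.95)
    ax.axvline(dist.threshold, color="tab:red", ls="--", lw=1, label="median + sd threshold")
    ax.set_xlabel("slope of cumulative count curve")
    ax.set_ylabel("scaled density" if scaled else "frequency")
    ax.legend(frameon=False)
    return ax
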