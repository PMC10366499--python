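"""Barcode ranking, knee-based cell-number estimation and curve truncation.

The contamination metrics operate on the *normalized cumulative-count
curve*: barcodes are sorted by descending total UMI count, the dataset
is truncated to a fixed multiple (default 4x) of the estimated real-cell
number so that samples with different numbers of encapsulated cells
become comparable, and both rank and cumulative count are normalized to
(0, 1].  The real-cell number is estimated as the first inflection
(knee) of cumulative counts versus log-ranked barcodes, or supplied by
the user.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import LowConfidenceKneeWarning, NoCountsError, ParameterError
from .io import CountMatrix

__all__ = ["RankedCurve", "rank_barcodes", "estimate_cell_number", "truncate_and_normalize"]


@dataclass
class RankedCurve:
    """Normalized cumulative-count curve over ranked, truncated barcodes.

    ``totals`` are the retained per-barcode totals sorted descending;
    ``x[i] = (i+1)/N`` are normalized rank positions and ``c`` the
    normalized cumulative totals, both in (0, 1] with ``c[-1] == 1``.
    """

    totals: np.ndarray
    x: np.ndarray
    c: np.ndarray
    n_cells_est: int
    multiple: int
    N: int

    def __post_init__(self) -> None:
        self.totals = np.asarray(self.totals, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if np.any(np.diff(self.totals) > 0):
            raise ValueError("totals must be non-increasing")
        if np.any(np.diff(self.c) < -1e-12):
            raise ValueError("cumulative curve must be non-decreasing")
        if abs(self.c[-1] - 1.0) > 1e-9:
            raise ValueError("cumulative curve must end at 1")

    @classmethod
    def from_totals(
        cls, totals_sorted: np.ndarray, n_cells_est: int, multiple: int = 4
    ) -> "RankedCurve":
        totals_sorted = np.asarray(totals_sorted, dtype=np.int64)
        n = len(totals_sorted)
        csum = np.cumsum(totals_sorted, dtype=np.float64)
        if csum[-1] <= 0:
            raise NoCountsError("no counts in the retained barcodes")
        return cls(
            totals=totals_sorted,
            x=np.arange(1, n + 1, dtype=float) / n,
            c=csum / csum[-1],
            n_cells_est=int(n_cells_est),
            multiple=int(multiple),
            N=n,
        )


def rank_barcodes(counts: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Sort barcodes by descending total UMI count.

    Returns ``(totals_sorted, order)`` where ``order`` indexes the
    original barcode axis.  The sort is stable: ties keep their original
    barcode order.
    """
    totals = counts.barcode_totals()
    if totals.sum() == 0:
        raise NoCountsError("no counts: every barcode has total UMI count 0")
    order = np.argsort(-totals, kind="stable")
    return totals[order], order


def estimate_cell_number(
    totals_sorted: np.ndarray,
    fallback_multiple: int = 4,
    window: int = 5,
) -> int:
    """Estimate the real-cell number from the first knee of the curve.

    Droplets capturing real cells contribute distinctly larger
    increments to the cumulative count than ambient-only droplets, so
    the first inflection of cumulative counts vs log10(rank) separates
    putative cells from empty droplets.  The knee is located as the
    maximum perpendicular distance between the normalized curve and the
    chord joining its endpoints: the distance series is smoothed with a
    centred moving average (window 5), the first local maximum is taken,
    and the estimate is refined to the unsmoothed maximum within one
    window of it.

    A curve with no distinct knee (maximum distance ~0, e.g. perfectly
    uniform totals) triggers a :class:`LowConfidenceKneeWarning` and the
    documented fallback ``n_barcodes / fallback_multiple``.
    """
    totals_sorted = np.asarray(totals_sorted)
    n_positive = int((totals_sorted > 0).sum())
    if n_positive < 3:
        raise ParameterError("need at least 3 barcodes with positive counts")
    # zero-count barcodes stay in: they form the flat tail that anchors
    # the knee when a dataset has no ambient counts at all
    m = len(totals_sorted)

    y = np.cumsum(totals_sorted, dtype=np.float64)
    y /= y[-1]
    xl = np.log10(np.arange(1, m + 1, dtype=np.float64))
    xn = xl / xl[-1]

    # signed perpendicular distance to the chord (positive above it)
    dx, dy = xn[-1] - xn[0], y[-1] - y[0]
    dist = (dx * (y - y[0]) - dy * (xn - xn[0])) / np.hypot(dx, dy)

    w = max(1, min(window, m))
    kernel = np.ones(w) / w
    smooth = np.convolve(dist, kernel, mode="same")

    if smooth.max() <= 1e-3:
        warnings.warn(
            "no distinct knee in the barcode-rank curve; falling back to "
            f"n_barcodes/{fallback_multiple}",
            LowConfidenceKneeWarning,
            stacklevel=2,
        )
        return max(1, int(round(n_positive / fallback_multiple)))

    peak = None
    for i in range(1, m - 1):
        if smooth[i] >= smooth[i - 1] and smooth[i] > smooth[i + 1]:
            peak = i
            break
    if peak is None:
        peak = int(np.argmax(smooth))
    lo, hi = max(0, peak - w), min(m, peak + w + 1)
    knee = lo + int(np.argmax(dist[lo:hi]))
    return knee + 1


def truncate_and_normalize(
    counts: CountMatrix,
    n_cells_est: int,
    multiple: int = 4,
) -> tuple[RankedCurve, CountMatrix]:
    """Keep the top ``multiple x n_cells_est`` barcodes; build the curve.

    Returns the normalized :class:`RankedCurve` plus the truncated
    CountMatrix (rows in rank order, same gene set) for the gene-level
    metrics.  If fewer barcodes are available than the cutoff, all are
    kept with a warning.
    """
    if n_cells_est < 1:
        raise ParameterError("n_cells_est must be >= 1")
    if multiple < 1:
        raise ParameterError("multiple must be >= 1")
    totals_sorted, order = rank_barcodes(counts)
    cutoff = int(multiple) * int(n_cells_est)
    n = counts.n_barcodes
    if cutoff > n:
        warnings.warn(
            f"requested {cutoff} barcodes ({multiple} x {n_cells_est}) but only "
            f"{n} available; keeping all",
            UserWarning,
            stacklevel=2,
        )
    N = min(cutoff, n)
    curve = RankedCurve.from_totals(totals_sorted[:N], n_cells_est, multiple)
    truncated = counts.subset_barcodes(order[:N])
    return curve, truncated
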