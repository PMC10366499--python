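"""Geometric contamination metrics from the normalized cumulative curve.

A clean dataset's cumulative-count curve rises steeply over the cell
ranks and then flattens, bowing far above the diagonal that joins the
origin to the last point; heavy ambient contamination flattens the
per-barcode increments and pulls the curve toward that diagonal.  Three
metrics quantify this, each inverted so that higher means more
contaminated:

* ``inverted_max_secant`` = 1 - max vertical curve-to-diagonal distance,
* ``inverted_secant_sd``  = 0.5 - population sd of those distances,
* ``inverted_auc_percentage`` = 2 x (1 - AUC / minimal-rectangle area).

On the normalized curve the minimal circumscribing rectangle has area 1,
and the secant-distance sd is bounded by 0.5 even for adversarial
three-point curves, which justifies the subtraction constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rankcurve import RankedCurve

__all__ = [
    "SecantProfile",
    "secant_profile",
    "inverted_max_secant",
    "inverted_secant_sd",
    "inverted_auc_percentage",
]


@dataclass
class SecantProfile:
    """Vertical distances between the curve and the diagonal, per rank."""

    d: np.ndarray
    max_d: float
    sd_d: float


def secant_profile(curve: RankedCurve) -> SecantProfile:
    """Per-rank vertical secant distances ``d_i = c_i - x_i``.

    After normalization the diagonal is ``y = x``, so the vertical
    distance of each curve point to it is simply ``c_i - x_i``; concave
    curves keep every distance non-negative (tiny negative float noise
    is clamped to 0).  Maximum and *population* standard deviation are
    taken over all retained ranks.
    """
    d = np.maximum(curve.c - curve.x, 0.0)
    return SecantProfile(d=d, max_d=float(d.max()), sd_d=float(d.std()))


def inverted_max_secant(profile: SecantProfile) -> float:
    """1 - max secant distance; higher = more contaminated, range [0, 1]."""
    return 1.0 - profile.max_d


def inverted_secant_sd(profile: SecantProfile) -> float:
    """0.5 - secant-distance sd; higher = more contaminated, range [0, 0.5]."""
    return 0.5 - profile.sd_d


def inverted_auc_percentage(curve: RankedCurve) -> float:
    """2 x (1 - AUC percentage) of the cumulative curve; range [0, 1].

    The AUC is computed by the trapezoidal rule on the normalized curve
    with the origin prepended (the diagonal is anchored at the origin
    too).  On the normalized curve the minimal circumscribing rectangle
    (number of barcodes x maximum cumulative count) has area 1, so the
    AUC percentage equals the AUC itself: 1 for a step curve (all mass
    in the first barcode), 0.5 for the diagonal (all noise), whence the
    doubling maps the result onto [0, 1].
    """
    x = np.concatenate(([0.0], curve.x))
    c = np.concatenate(([0.0], curve.c))
    auc = float(np.trapezoid(c, x))
    return 2.0 * (1.0 - auc)
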