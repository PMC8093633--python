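"""Axial (pi-periodic) angle utilities.

Cell and fiber orientations are axes, not directions: an orientation theta
and theta + pi describe the same physical state.  Every public angle in this
package is therefore stored wrapped into the half-open interval
``(-pi/2, pi/2]`` and angular arithmetic is carried out modulo pi.  Circular
summary statistics (mean direction, resultant length, concentration) are
computed on the doubled-angle circle, the standard construction for axial
data.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_axial",
    "axial_difference",
    "axial_mean",
    "axial_resultant_length",
    "estimate_concentration",
    "orientation_histogram",
]


def wrap_axial(theta):
    """Wrap angles into the axial interval ``(-pi/2, pi/2]``.

    Accepts scalars or arrays; returns the same shape.
    """
    theta = np.asarray(theta, dtype=float)
    wrapped = theta - np.pi * np.ceil(theta / np.pi - 0.5)
    return wrapped if wrapped.ndim else float(wrapped)


def axial_difference(a, b):
    """Shortest signed axial difference ``a - b`` modulo pi.

    The result lies in ``[-pi/2, pi/2)``; its sign is the direction of the
    shortest rotation taking axis ``b`` onto axis ``a``.
    """
    d = np.mod(np.asarray(a, float) - np.asarray(b, float) + np.pi / 2.0, np.pi) - np.pi / 2.0
    return d if d.ndim else float(d)


def _doubled_resultant(angles, weights=None):
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("need at least one angle")
    if weights is None:
        c = np.mean(np.cos(2.0 * angles))
        s = np.mean(np.sin(2.0 * angles))
    else:
        weights = np.asarray(weights, dtype=float)
        total = weights.sum()
        c = float(np.sum(weights * np.cos(2.0 * angles)) / total)
        s = float(np.sum(weights * np.sin(2.0 * angles)) / total)
    return c, s


def axial_mean(angles, weights=None):
    """Mean axis of a sample of axial angles, in ``(-pi/2, pi/2]``."""
    c, s = _doubled_resultant(angles, weights)
    return wrap_axial(0.5 * np.arctan2(s, c))


def axial_resultant_length(angles, weights=None):
    """Mean resultant length ``R`` of the doubled angles, in [0, 1].

    ``R = 0`` for perfectly dispersed axes, ``R = 1`` for perfect alignment.
    """
    c, s = _doubled_resultant(angles, weights)
    return float(np.hypot(c, s))


def estimate_concentration(angles):
    """Estimate a von Mises concentration parameter from axial data.

    Uses the standard Fisher approximation to invert the mean resultant
    length of the doubled angles.  Returns ``inf`` for degenerate
    (perfectly aligned) samples.
    """
    r = axial_resultant_length(angles)
    if r >= 1.0 - 1e-12:
        return float("inf")
    if r < 0.53:
        kappa = 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    elif r < 0.85:
        kappa = -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    else:
        kappa = 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)
    return float(kappa)


def orientation_histogram(angles, bin_width_deg: float = 10.0):
    """Histogram of axial angles over ``[-90, 90)`` degrees.

    Returns ``(counts, edges_deg)``; the bin width defaults to 10 degrees.
    +90 degrees is the same axis as -90 and is counted in the first bin.
    """
    deg = np.degrees(wrap_axial(np.asarray(angles, dtype=float)))
    deg = np.where(deg >= 90.0, deg - 180.0, deg)
    edges = np.arange(-90.0, 90.0 + bin_width_deg / 2.0, bin_width_deg)
    counts, _ = np.histogram(deg, bins=edges)
    return counts, edges
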