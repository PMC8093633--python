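"""Cyclic-strain kinematics: Mohr's-circle decomposition and per-cell stimulus.

The substrate is loaded with a prescribed engineering-strain cycle given by
the x, y and shear components at the two extremes of the cycle.  The cycle is
summarised by a mean tensor (midpoint of the two extremes) and an amplitude
tensor, whose principal decomposition yields the maximum principal strain
amplitude and its direction.  Cells "strain avoid": their preferred axis
under strain is perpendicular to the maximum principal strain direction.

Amplitude convention
--------------------
A stretch cycle labelled "0-10%" can be read either as an amplitude tensor of
``(max - min) / 2`` per component (the oscillation about the mean,
``convention="half-range"``) or as the full excursion ``max - min``
(``convention="peak-to-peak"``).  Both are supported; the package default is
the half-range convention, under which the shipped turnover parameters were
calibrated (see ``docs/methods.md``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import wrap_axial

__all__ = [
    "DEFAULT_CONVENTION",
    "AppliedStrain",
    "PrincipalStrain",
    "mohr_decompose",
    "effective_strain",
    "effective_stimulus",
]

#: Default reading of a strain cycle's amplitude ("half-range" or "peak-to-peak").
DEFAULT_CONVENTION = "half-range"

_CONVENTIONS = ("half-range", "peak-to-peak")


@dataclass(frozen=True)
class AppliedStrain:
    """Engineering-strain components at the two extremes of a loading cycle.

    All components are dimensionless engineering strains; each ``*_max`` must
    be at least the corresponding ``*_min`` and all magnitudes must be below 1.
    """

    eps_x_min: float = 0.0
    eps_x_max: float = 0.0
    eps_y_min: float = 0.0
    eps_y_max: float = 0.0
    gamma_xy_min: float = 0.0
    gamma_xy_max: float = 0.0

    def __post_init__(self):
        vals = (
            self.eps_x_min,
            self.eps_x_max,
            self.eps_y_min,
            self.eps_y_max,
            self.gamma_xy_min,
            self.gamma_xy_max,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("strain components must be finite")
        if any(abs(v) >= 1.0 for v in vals):
            raise ValueError("engineering strain magnitudes must lie in [0, 1)")
        for lo, hi, name in (
            (self.eps_x_min, self.eps_x_max, "eps_x"),
            (self.eps_y_min, self.eps_y_max, "eps_y"),
            (self.gamma_xy_min, self.gamma_xy_max, "gamma_xy"),
        ):
            if hi < lo:
                raise ValueError(f"{name}_max must be >= {name}_min")

    @classmethod
    def zero(cls) -> "AppliedStrain":
        return cls()

    @classmethod
    def uniaxial_x(cls, lo: float, hi: float) -> "AppliedStrain":
        """Uniaxial stretch cycle along x, e.g. ``uniaxial_x(0.0, 0.10)`` for 0-10%."""
        return cls(eps_x_min=lo, eps_x_max=hi)

    def mean_components(self) -> tuple[float, float, float]:
        """Midpoint-of-cycle tensor components ``(eps_x, eps_y, gamma_xy)``."""
        return (
            0.5 * (self.eps_x_min + self.eps_x_max),
            0.5 * (self.eps_y_min + self.eps_y_max),
            0.5 * (self.gamma_xy_min + self.gamma_xy_max),
        )

    def amplitude_components(self, convention: str = DEFAULT_CONVENTION):
        """Amplitude tensor components under the given convention."""
        if convention not in _CONVENTIONS:
            raise ValueError(f"unknown strain convention {convention!r}")
        scale = 0.5 if convention == "half-range" else 1.0
        return (
            scale * (self.eps_x_max - self.eps_x_min),
            scale * (self.eps_y_max - self.eps_y_min),
            scale * (self.gamma_xy_max - self.gamma_xy_min),
        )


@dataclass(frozen=True)
class PrincipalStrain:
    """Principal description of the strain cycle's amplitude tensor.

    ``theta_p`` is the direction of the maximum principal strain amplitude and
    ``theta_csa`` the strain-avoidance axis, perpendicular to it; both lie in
    ``(-pi/2, pi/2]``.
    """

    eps_max: float
    eps_min: float
    theta_p: float
    theta_csa: float


def mohr_decompose(
    applied: AppliedStrain, convention: str = DEFAULT_CONVENTION
) -> PrincipalStrain:
    """Principal strain amplitudes and directions via Mohr's circle.

    The amplitude tensor ``(exx, eyy, gxy)`` is reduced to its principal
    values ``centre +/- radius`` with ``radius = sqrt(((exx-eyy)/2)^2 +
    (gxy/2)^2)``.  For an isotropic (equibiaxial) amplitude the principal
    direction is degenerate and reported as 0 by convention.
    """
    exx, eyy, gxy = applied.amplitude_components(convention)
    centre = 0.5 * (exx + eyy)
    radius = float(np.hypot(0.5 * (exx - eyy), 0.5 * gxy))
    if radius < 1e-15:
        theta_p = 0.0
    else:
        theta_p = wrap_axial(0.5 * np.arctan2(gxy, exx - eyy))
    return PrincipalStrain(
        eps_max=centre + radius,
        eps_min=centre - radius,
        theta_p=theta_p,
        theta_csa=wrap_axial(theta_p + np.pi / 2.0),
    )


def effective_strain(delta_eps, theta_cell, theta_p):
    """Strain amplitude resolved along a cell's axis.

    ``eps_eff = delta_eps * |cos(theta_cell - theta_p)|``.  The absolute value
    reflects that cell orientations are axes: a cell at +60 and one at -120
    degrees to the principal direction experience the same stretch, and a
    negative "experienced strain" has no physical meaning.
    """
    delta_eps = np.asarray(delta_eps, dtype=float)
    alpha = np.asarray(theta_cell, dtype=float) - np.asarray(theta_p, dtype=float)
    if not np.all(np.isfinite(delta_eps)) or not np.all(np.isfinite(alpha)):
        raise ValueError("non-finite input to effective_strain")
    out = delta_eps * np.abs(np.cos(alpha))
    return out if out.ndim else float(out)


def effective_stimulus(eps_eff, eps_thres: float, eps_max_param: float):
    """Rescale an effective strain into the stimulus ``Z_eff`` in [0, 1].

    Linear between the threshold strain (below which cells do not respond)
    and the saturation strain (above which a cell already reorients as fast
    as it can); clamped outside that band.
    """
    if not (np.isfinite(eps_thres) and np.isfinite(eps_max_param)):
        raise ValueError("strain thresholds must be finite")
    if eps_thres < 0.0 or eps_max_param <= eps_thres:
        raise ValueError("require eps_max_param > eps_thres >= 0")
    eps_eff = np.asarray(eps_eff, dtype=float)
    z = np.clip((eps_eff - eps_thres) / (eps_max_param - eps_thres), 0.0, 1.0)
    return z if z.ndim else float(z)
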