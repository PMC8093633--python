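"""Synthetic collagen-fiber orientation fields.

A structured substrate (e.g. decellularised arterial tissue) presents cells
with a smooth but spatially varying field of fiber orientations.  The field
is synthesised by scattering vertices over the rectangular domain, drawing
one axial von Mises angle per vertex (mean direction ``theta_fb``,
concentration ``kappa``), triangulating the vertices with Delaunay, and
interpolating angles inside each triangle with linear shape functions.

Because fiber orientations are axes, both the sampling and the interpolation
work on doubled angles: vertex angles are mapped to unit vectors
``(cos 2*theta, sin 2*theta)``, the vectors are blended with barycentric
weights, and the resultant is halved back.  This avoids the wrap artefacts a
naive scalar interpolation would produce near +/- pi/2.

The scalar fiber density ``phi_f`` is carried alongside the orientation
field: 0 for a bare elastomer (PDMS), 1 for dense collagenous tissue.  It is
a single constant per field in this version.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .angles import wrap_axial

__all__ = ["FiberField", "sample_von_mises", "build_fiber_field"]


def sample_von_mises(mean: float, kappa: float, n: int, rng) -> np.ndarray:
    """Draw ``n`` axial angles from a von Mises distribution.

    ``kappa`` is the concentration of the doubled-angle distribution (the
    standard axial von Mises construction): doubled angles are drawn from
    ``VM(2 * mean, kappa)`` and halved.  ``kappa = 0`` gives circular-uniform
    axes.  ``rng`` is a :class:`numpy.random.Generator` or a seed.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if kappa == 0:
        doubled = rng.uniform(-np.pi, np.pi, size=n)
    else:
        doubled = rng.vonmises(wrap_axial(mean) * 2.0, kappa, size=n)
    return wrap_axial(0.5 * doubled)


@dataclass
class FiberField:
    """A triangulated, continuously interpolated fiber-orientation field."""

    mean_direction: float
    kappa: float
    density: float
    points: np.ndarray  # (n, 2) vertex coordinates, um
    angles: np.ndarray  # (n,) axial angle per vertex, rad
    width: float
    height: float
    triangulation: Delaunay = field(repr=False, default=None)

    def __post_init__(self):
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("fiber density must lie in [0, 1]")
        if self.triangulation is None:
            self.triangulation = Delaunay(self.points)

    def query(self, points) -> np.ndarray:
        """Interpolated fiber angle at one or more points inside the domain.

        Raises ``ValueError`` for points outside the triangulated domain.
        Boundary points are assigned by Delaunay's deterministic simplex
        lookup, so ties on shared edges resolve reproducibly.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        simplex = self.triangulation.find_simplex(pts)
        if np.any(simplex < 0):
            raise ValueError("query point outside the fiber field domain")
        # barycentric weights from the cached affine transform
        transform = self.triangulation.transform[simplex]
        b = np.einsum("nij,nj->ni", transform[:, :2], pts - transform[:, 2])
        weights = np.column_stack([b, 1.0 - b.sum(axis=1)])
        verts = self.triangulation.simplices[simplex]
        doubled = 2.0 * self.angles[verts]
        c = np.sum(weights * np.cos(doubled), axis=1)
        s = np.sum(weights * np.sin(doubled), axis=1)
        # Antipodal cancellation (resultant ~ 0) can only occur for vertex
        # angles spread by ~pi/2 within one triangle; fall back to the
        # dominant-weight vertex there.
        norm = np.hypot(c, s)
        out = wrap_axial(0.5 * np.arctan2(s, c))
        degenerate = norm < 1e-12
        if np.any(degenerate):
            lead = verts[degenerate, np.argmax(weights[degenerate], axis=1)]
            out = np.asarray(out)
            out[degenerate] = self.angles[lead]
        out = np.asarray(out)
        return out if np.asarray(points).ndim > 1 else float(out[0])

    def export_vertices(self, path) -> None:
        """Write the vertex mesh as CSV columns ``x, y, angle_rad``."""
        import pandas as pd

        pd.DataFrame(
            {"x": self.points[:, 0], "y": self.points[:, 1], "angle_rad": self.angles}
        ).to_csv(path, index=False)

    def rasterize(self, nx: int = 50, ny: int = 50) -> np.ndarray:
        """Angle grid sampled on an ``ny x nx`` lattice (for plotting)."""
        xs = np.linspace(0.0, self.width, nx)
        ys = np.linspace(0.0, self.height, ny)
        gx, gy = np.meshgrid(xs, ys)
        return self.query(np.column_stack([gx.ravel(), gy.ravel()])).reshape(ny, nx)


def build_fiber_field(
    width: float,
    height: float,
    mean_direction: float,
    kappa: float,
    density: float = 1.0,
    n_interior: int = 200,
    rng=None,
) -> FiberField:
    """Synthesise a fiber field over a ``width x height`` rectangle.

    ``n_interior`` uniformly random interior vertices plus the four domain
    corners are triangulated so the whole rectangle is covered.  One axial
    von Mises draw is assigned per vertex.  Degenerate (collinear) vertex
    sets are re-drawn; with zero interior vertices the corners alone give
    the minimal two-triangle cover.
    """
    if n_interior < 0:
        raise ValueError("n_interior must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    corners = np.array(
        [[0.0, 0.0], [width, 0.0], [0.0, height], [width, height]], dtype=float
    )
    for _ in range(5):
        interior = rng.uniform((0.0, 0.0), (width, height), size=(n_interior, 2))
        points = np.vstack([corners, interior])
        try:
            tri = Delaunay(points)
        except QhullError:  # pragma: no cover - needs pathological draws
            continue
        angles = sample_von_mises(mean_direction, kappa, len(points), rng)
        return FiberField(
            mean_direction=wrap_axial(mean_direction),
            kappa=float(kappa),
            density=float(density),
            points=points,
            angles=np.asarray(angles, dtype=float),
            width=float(width),
            height=float(height),
            triangulation=tri,
        )
    raise ValueError("could not build a non-degenerate triangulation")
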