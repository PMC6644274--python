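"""Meridional circle geometry of the crystalline lens.

The anterior and posterior surfaces of the crystalline lens, seen in a
meridional AS-OCT section, are modelled as circular arcs.  All depths are
measured in millimetres along the eye axis from the posterior corneal
vertex, positive toward the retina; heights are measured perpendicular to
that axis.  Corneal thickness is excluded throughout.

Three quantities summarise the axial position of the lens:

* ASD — anterior surface depth, the anterior circle's vertex;
* PSD — posterior surface depth, the posterior circle's vertex
  (``PSD = ASD + LT`` by construction, LT the lens thickness);
* ESD — equatorial surface depth, the depth of the plane through the two
  points where the fitted anterior and posterior circles intersect.

For circles with on-axis centres ``(z_a, R_a)`` and ``(z_p, R_p)`` the
intersection points share the depth

    z* = (z_a^2 − z_p^2 − R_a^2 + R_p^2) / (2 (z_a − z_p)),

the radical plane of the two circles restricted to a genuinely
intersecting pair.  ``equatorial_depth`` implements this closed form and
refuses non-intersecting configurations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "DegenerateSamplesError",
    "SurfaceTiltError",
    "NonIntersectingCirclesError",
    "AxisCircle",
    "SurfaceSamples",
    "LensShape",
    "fit_circle",
    "equatorial_depth",
    "equatorial_depth_batch",
    "lens_shape_from_circles",
    "DEFAULT_TILT_TOLERANCE_MM",
]

#: Maximum |height| of a fitted circle centre before the surface is
#: considered tilted relative to the measurement axis (mm).
DEFAULT_TILT_TOLERANCE_MM = 0.2


class GeometryError(ValueError):
    """Invalid or degenerate lens geometry."""


class DegenerateSamplesError(GeometryError):
    """Fewer than three samples, or collinear samples."""


class SurfaceTiltError(GeometryError):
    """Fitted circle centre lies too far off the measurement axis."""


class NonIntersectingCirclesError(GeometryError):
    """The two surface circles have no real intersection point."""


@dataclass(frozen=True)
class AxisCircle:
    """A lens surface circle with its centre on the measurement axis.

    Parameters
    ----------
    center_depth
        Depth of the circle centre, mm from the posterior corneal vertex.
    radius
        Circle radius, mm; must be positive.
    """

    center_depth: float
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise GeometryError(f"radius must be positive, got {self.radius}")

    @property
    def anterior_vertex(self) -> float:
        """Depth of the vertex facing the cornea (``center_depth − radius``)."""
        return self.center_depth - self.radius

    @property
    def posterior_vertex(self) -> float:
        """Depth of the vertex facing the retina (``center_depth + radius``)."""
        return self.center_depth + self.radius


@dataclass(frozen=True)
class SurfaceSamples:
    """Sampled points on one lens surface within the pupil aperture.

    ``points`` is an ``(n, 2)`` array of ``(depth_mm, height_mm)`` pairs;
    heights must lie within ``±aperture_mm / 2``.
    """

    points: np.ndarray
    aperture_mm: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise GeometryError("points must be an (n, 2) array of (depth, height)")
        if not self.aperture_mm > 0:
            raise GeometryError("invalid aperture")
        if np.any(np.abs(pts[:, 1]) > self.aperture_mm / 2 + 1e-9):
            raise GeometryError("sample heights exceed the aperture half-width")
        object.__setattr__(self, "points", pts)

    @classmethod
    def from_csv(cls, path, aperture_mm: float | None = None) -> "SurfaceSamples":
        """Read ``depth_mm,height_mm`` two-column CSV into samples.

        When ``aperture_mm`` is omitted it is taken as twice the largest
        absolute sampled height.
        """
        import pandas as pd

        df = pd.read_csv(path)
        pts = df[["depth_mm", "height_mm"]].to_numpy(dtype=float)
        if aperture_mm is None:
            aperture_mm = 2.0 * float(np.max(np.abs(pts[:, 1])))
        return cls(points=pts, aperture_mm=aperture_mm)


@dataclass(frozen=True)
class LensShape:
    """Preoperative crystalline-lens geometry.

    All fields in mm: anterior/posterior curvature radii (``acr_mm``,
    ``pcr_mm``), lens thickness ``lt_mm`` and the three surface depths.
    Invariants: ``psd = asd + lt`` exactly and ``asd < esd < psd``.
    """

    acr_mm: float
    pcr_mm: float
    lt_mm: float
    asd_mm: float
    esd_mm: float
    psd_mm: float

    def __post_init__(self) -> None:
        for name in ("acr_mm", "pcr_mm", "lt_mm", "asd_mm"):
            if not getattr(self, name) > 0:
                raise GeometryError(f"{name} must be positive")
        if abs(self.psd_mm - (self.asd_mm + self.lt_mm)) > 1e-9:
            raise GeometryError("psd must equal asd + lt")
        if not (self.asd_mm < self.esd_mm < self.psd_mm):
            raise GeometryError("esd must lie strictly between asd and psd")


def fit_circle(
    samples: SurfaceSamples,
    tilt_tolerance_mm: float = DEFAULT_TILT_TOLERANCE_MM,
) -> AxisCircle:
    """Least-squares circle through surface samples, collapsed onto the axis.

    Uses the algebraic (Kåsa) objective: with ``z`` the depth and ``h`` the
    height coordinate, solve the linear least-squares problem

        z^2 + h^2 + D z + E h + F ≈ 0

    for ``(D, E, F)``; the centre is ``(−D/2, −E/2)`` and the radius
    ``sqrt(D^2/4 + E^2/4 − F)``.  Closed-form and deterministic; adequate
    for the shallow arcs a pupil-limited aperture yields.  (A Pratt or
    Taubin refinement could be substituted without changing the interface.)

    The fitted centre height must be within ``tilt_tolerance_mm`` of the
    axis; otherwise the surface is deemed tilted and a
    :class:`SurfaceTiltError` is raised rather than silently projecting.

    Raises
    ------
    DegenerateSamplesError
        Fewer than three points, or collinear points.
    SurfaceTiltError
        ``|centre height| > tilt_tolerance_mm``.
    """
    pts = samples.points
    if len(pts) < 3:
        raise DegenerateSamplesError("degenerate samples: need at least 3 points")
    z, h = pts[:, 0], pts[:, 1]
    centred = pts - pts.mean(axis=0)
    # Collinear points span a rank-1 subspace after centring.
    if np.linalg.matrix_rank(centred, tol=1e-10 * max(1.0, np.abs(pts).max())) < 2:
        raise DegenerateSamplesError("degenerate samples: points are collinear")
    a = np.column_stack([z, h, np.ones_like(z)])
    b = -(z**2 + h**2)
    (d, e, f), *_ = np.linalg.lstsq(a, b, rcond=None)
    center_depth = -d / 2.0
    center_height = -e / 2.0
    radius_sq = center_depth**2 + center_height**2 - f
    if radius_sq <= 0:
        raise DegenerateSamplesError("degenerate samples: non-positive fitted radius")
    if abs(center_height) > tilt_tolerance_mm:
        raise SurfaceTiltError(
            f"surface tilt exceeds tolerance: centre height "
            f"{center_height:.4f} mm > {tilt_tolerance_mm} mm"
        )
    return AxisCircle(center_depth=float(center_depth), radius=float(np.sqrt(radius_sq)))


def equatorial_depth(anterior: AxisCircle, posterior: AxisCircle) -> float:
    """Depth of the plane through the two circle–circle intersection points.

    Parameters
    ----------
    anterior, posterior
        The fitted anterior and posterior surface circles.

    Returns
    -------
    float
        ESD in mm.  Satisfies ``asd < esd < psd`` for any valid lens.

    Raises
    ------
    GeometryError
        Equal centre depths (equator undefined) or a depth outside the
        lens vertices.
    NonIntersectingCirclesError
        The circles have no real intersection.
    """
    z_a, r_a = anterior.center_depth, anterior.radius
    z_p, r_p = posterior.center_depth, posterior.radius
    if z_a == z_p:
        raise GeometryError("concentric-depth circles, equator undefined")
    z_star = (z_a**2 - z_p**2 - r_a**2 + r_p**2) / (2.0 * (z_a - z_p))
    if r_a**2 - (z_star - z_a) ** 2 <= 0:
        raise NonIntersectingCirclesError("lens circles do not intersect")
    asd = anterior.anterior_vertex
    psd = posterior.posterior_vertex
    if not (asd < z_star < psd):
        raise GeometryError("equatorial plane falls outside the lens vertices")
    return float(z_star)


def equatorial_depth_batch(
    z_a: np.ndarray, r_a: np.ndarray, z_p: np.ndarray, r_p: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised radical-plane depth for arrays of circle pairs.

    Returns ``(depth, valid)`` where ``valid`` flags pairs whose circles
    genuinely intersect with the equator between the lens vertices; the
    depth is NaN where invalid.  Same construction as
    :func:`equatorial_depth`, exposed for cohort-scale use.
    """
    z_a, r_a, z_p, r_p = map(np.asarray, (z_a, r_a, z_p, r_p))
    dz = z_a - z_p
    with np.errstate(divide="ignore", invalid="ignore"):
        z_star = (z_a**2 - z_p**2 - r_a**2 + r_p**2) / (2.0 * dz)
    asd = z_a - r_a
    psd = z_p + r_p
    valid = (
        (dz != 0)
        & (r_a > 0)
        & (r_p > 0)
        & (r_a**2 - (z_star - z_a) ** 2 > 0)
        & (z_star > asd)
        & (z_star < psd)
    )
    return np.where(valid, z_star, np.nan), valid


def lens_shape_from_circles(anterior: AxisCircle, posterior: AxisCircle) -> LensShape:
    """Assemble a :class:`LensShape` from the two fitted surface circles.

    ``asd`` is the anterior circle's corneal-side vertex, ``psd`` the
    posterior circle's retinal-side vertex, ``lt = psd − asd`` and ``esd``
    the radical-plane depth of :func:`equatorial_depth`.
    """
    asd = anterior.anterior_vertex
    psd = posterior.posterior_vertex
    lt = psd - asd
    if lt <= 0:
        raise GeometryError("inverted lens geometry")
    esd = equatorial_depth(anterior, posterior)
    return LensShape(
        acr_mm=anterior.radius,
        pcr_mm=posterior.radius,
        lt_mm=lt,
        asd_mm=asd,
        esd_mm=esd,
        psd_mm=psd,
    )
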