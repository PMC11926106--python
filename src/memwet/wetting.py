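"""Fluid-elastic wetting parameters from vesicle-condensate cross-sections.

A condensate droplet partially wetting a giant vesicle divides the membrane
into two spherical-cap segments.  In the equatorial cross-section the three
interfaces appear as circular arcs meeting at two contact points:

* ``ie`` - membrane facing the external buffer,
* ``ic`` - membrane facing the condensate (may be nearly flat),
* ``ce`` - free condensate surface facing the buffer.

At a contact point the three interfacial tensions (Sigma_ce and the two
membrane segment tensions Sigma_ie, Sigma_ic) balance, closing a force
triangle.  The three apparent contact angles theta_i, theta_e, theta_c -
the sector angles opened toward the vesicle interior, the external solution
and the condensate - therefore satisfy theta_i + theta_e + theta_c = 360
degrees and, by the law of sines,

    Sigma_ie / Sigma_ce = sin(theta_c) / sin(theta_i)
    Sigma_ic / Sigma_ce = sin(theta_e) / sin(theta_i)

The geometric factor

    Phi = (sin(theta_e) - sin(theta_c)) / sin(theta_i),  -1 <= Phi <= 1

is a material parameter independent of vesicle/droplet size: Phi = +1 at
dewetting, Phi = -1 at complete wetting.  It equals the cosine of the
intrinsic contact angle theta_e_in (the nanoscale wetting angle) and the
rescaled affinity contrast W / Sigma_ce, where W = W_ic - W_ie compares the
adhesion free energies per unit area of the two membrane segments.  Given a
measured condensate interfacial tension Sigma_ce, W and the two segment
tensions follow directly from the angles.  The common membrane tension
Sigma and the individual adhesion parameters W_ic, W_ie enter only through
the sums Sigma_ie = Sigma + W_ie and Sigma_ic = Sigma + W_ic and are not
individually identifiable from angles plus Sigma_ce; only their difference
W is reported.

Angles are degrees in the public API and radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ContourSet",
    "CircleModel",
    "ContactAngles",
    "WettingGeometry",
    "GeometryReport",
    "GeometryError",
    "fit_circle",
    "apparent_angles",
    "geometric_factor",
    "intrinsic_angle",
    "geometric_factor_from_intrinsic",
    "affinity_contrast",
    "segment_tensions",
    "tension_triangle_angles",
    "wetting_parameters",
    "validate_geometry",
]


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent wetting geometry."""


@dataclass(frozen=True)
class ContourSet:
    """Labelled contour points of the three interfaces of one cross-section.

    Coordinates are in micrometres (x right, y down when derived from image
    pixels).  ``pixel_size`` records the micrometres-per-pixel calibration of
    the source image.
    """

    arc_ie: np.ndarray
    arc_ic: np.ndarray
    arc_ce: np.ndarray
    pixel_size: float = 1.0
    image_id: str = ""

    def __post_init__(self) -> None:
        for name in ("arc_ie", "arc_ic", "arc_ce"):
            pts = np.asarray(getattr(self, name), dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
                raise GeometryError(f"{name} needs at least 3 (x, y) points")
            object.__setattr__(self, name, pts)
        if self.pixel_size <= 0:
            raise GeometryError("pixel_size must be > 0")


@dataclass(frozen=True)
class CircleModel:
    """Least-squares circle (or straight-line fallback for flat interfaces)."""

    center: tuple[float, float] | None
    radius: float | None
    rms_residual: float
    is_line: bool = False
    line_point: tuple[float, float] | None = None
    line_dir: tuple[float, float] | None = None

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Orthogonal deviation of points from the model curve."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.is_line:
            p0 = np.asarray(self.line_point)
            d = np.asarray(self.line_dir)
            n = np.array([-d[1], d[0]])
            return (pts - p0) @ n
        c = np.asarray(self.center)
        return np.hypot(*(pts - c).T) - self.radius


@dataclass(frozen=True)
class ContactAngles:
    """Apparent contact angles (degrees) at the three-phase contact line.

    ``asymmetry_deg`` is the largest left/right contact-point disagreement
    when the angles were averaged over both contact points of an equatorial
    cross-section (0 for synthetic single-point evaluation).
    """

    theta_i: float
    theta_e: float
    theta_c: float
    asymmetry_deg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("theta_i", "theta_e", "theta_c"):
            v = float(getattr(self, name))
            if not (0.0 < v < 360.0):
                raise GeometryError(f"{name}={v} outside (0, 360) degrees")
            object.__setattr__(self, name, v)

    @property
    def angle_sum(self) -> float:
        return self.theta_i + self.theta_e + self.theta_c

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.theta_i, self.theta_e, self.theta_c)


@dataclass(frozen=True)
class WettingGeometry:
    """Derived fluid-elastic parameters of one vesicle-condensate couple.

    Tensions carry the units of ``sigma_ce`` (conventionally uN/m).
    """

    angles: ContactAngles
    phi: float
    theta_e_in: float
    sigma_ce: float
    affinity_contrast: float
    sigma_ie: float
    sigma_ic: float


@dataclass(frozen=True)
class GeometryReport:
    """Consistency checks on a measured angle triple."""

    angle_sum_deg: float
    angle_sum_deviation_deg: float
    angle_sum_ok: bool
    phi: float | None
    phi_in_range: bool
    closure_residual: float | None  # |vector sum of tensions| / sigma_ce
    closure_ok: bool
    flags: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.flags


# ---------------------------------------------------------------------------
# circle fitting


def fit_circle(points: np.ndarray, allow_line: bool = True,
               curvature_threshold: float | None = None) -> CircleModel:
    """Fit a circle to 2-D points with the algebraic Taubin method.

    The Taubin fit solves the gradient-weighted algebraic least-squares
    problem and is nearly unbiased on short arcs, which matters here because
    interface arcs typically subtend well under a full circle.  When the
    fitted curvature falls below ``curvature_threshold`` the interface is
    treated as flat and a total-least-squares line is returned instead
    (``is_line=True``) - the partial-wetting limit where the
    membrane-condensate interface loses visible curvature.  Replacing a
    finite-radius arc by its chord biases the endpoint tangent by half the
    subtended angle, so the default threshold, 1 / (1000 x bounding-box
    diagonal of the arc), only flattens arcs whose tangent bias is
    negligible (< 0.03 degrees); callers wanting the coarser
    one-tenth-of-field-size rule can pass ``curvature_threshold``
    explicitly.

    Raises
    ------
    GeometryError
        Fewer than 3 points, or collinear points with ``allow_line=False``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise GeometryError("need at least 3 (x, y) points")
    centroid = pts.mean(axis=0)
    X = pts - centroid
    span = float(np.hypot(*(pts.max(axis=0) - pts.min(axis=0))))
    if span == 0.0:
        raise GeometryError("points are coincident")
    if curvature_threshold is None:
        curvature_threshold = 1.0 / (1000.0 * span)

    Z = (X**2).sum(axis=1)
    zmean = Z.mean()
    if zmean <= 0:
        raise GeometryError("points are coincident")
    Z0 = (Z - zmean) / (2.0 * math.sqrt(zmean))
    _, _, vt = np.linalg.svd(np.column_stack([Z0, X]), full_matrices=False)
    a0, a1, a2 = vt[2]
    A = a0 / (2.0 * math.sqrt(zmean))
    D = -zmean * A

    curvature_ok = abs(A) > 1e-15
    if curvature_ok:
        cx, cy = -a1 / (2.0 * A), -a2 / (2.0 * A)
        radius = math.sqrt(a1**2 + a2**2 - 4.0 * A * D) / (2.0 * abs(A))
        curvature = 1.0 / radius
    else:
        curvature = 0.0

    if curvature < curvature_threshold:
        if not allow_line:
            raise GeometryError("points are (near-)collinear and line fallback is disabled")
        return _fit_line(pts, centroid, X)

    center = (cx + centroid[0], cy + centroid[1])
    dist = np.hypot(X[:, 0] - cx, X[:, 1] - cy)
    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    return CircleModel(center=center, radius=float(radius), rms_residual=rms)


def _fit_line(pts: np.ndarray, centroid: np.ndarray, X: np.ndarray) -> CircleModel:
    # total least squares: principal direction of the centred points
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    d = vt[0]
    n = np.array([-d[1], d[0]])
    rms = float(np.sqrt(np.mean((X @ n) ** 2)))
    return CircleModel(center=None, radius=None, rms_residual=rms, is_line=True,
                       line_point=tuple(centroid), line_dir=(float(d[0]), float(d[1])))


# ---------------------------------------------------------------------------
# apparent contact angles from fitted interface models


def _circle_intersections(c1: CircleModel, c2: CircleModel) -> tuple[np.ndarray, np.ndarray]:
    p1, r1 = np.asarray(c1.center), c1.radius
    p2, r2 = np.asarray(c2.center), c2.radius
    d = float(np.hypot(*(p2 - p1)))
    if d == 0.0:
        raise GeometryError("no contact line: concentric interface circles")
    if d > r1 + r2 or d < abs(r1 - r2):
        raise GeometryError("no contact line: interface circles do not intersect")
    a = (d**2 + r1**2 - r2**2) / (2.0 * d)
    h2 = r1**2 - a**2
    h = math.sqrt(max(h2, 0.0))
    ex = (p2 - p1) / d
    ey = np.array([-ex[1], ex[0]])
    mid = p1 + a * ex
    return mid + h * ey, mid - h * ey


def _tangent(model: CircleModel, p: np.ndarray) -> np.ndarray:
    """Unit tangent line direction (sign unresolved) of the model at/near p."""
    if model.is_line:
        return np.asarray(model.line_dir, dtype=float)
    radial = p - np.asarray(model.center)
    t = np.array([-radial[1], radial[0]])
    nrm = np.hypot(*t)
    if nrm == 0.0:
        raise GeometryError("contact point coincides with a circle centre")
    return t / nrm


def _ccw_gap(a: float, b: float) -> float:
    """Counter-clockwise angle from ray a to ray b, in (0, 2*pi]."""
    g = (b - a) % (2.0 * math.pi)
    return g if g > 0 else 2.0 * math.pi


def _sector(psi_from: float, psi_to: float, psi_other: float) -> float:
    """Angle of the sector between two rays that does NOT contain the third."""
    g = _ccw_gap(psi_from, psi_to)
    inside = _ccw_gap(psi_from, psi_other) < g
    return 2.0 * math.pi - g if inside else g


def _angles_at_point(p: np.ndarray, circle_ie: CircleModel, circle_ic: CircleModel,
                     circle_ce: CircleModel) -> tuple[float, float, float]:
    c_ie = np.asarray(circle_ie.center)
    c_ce = np.asarray(circle_ce.center)
    # into-arc tangent rays: the ie arc leaves the condensate disc, the ce arc
    # leaves the vesicle disc, the ic arc runs under the condensate (into the
    # ce disc).  Signs follow from d/ds of the distance to the relevant centre.
    t_ie = _tangent(circle_ie, p)
    if t_ie @ (p - c_ce) < 0:
        t_ie = -t_ie
    t_ce = _tangent(circle_ce, p)
    if t_ce @ (p - c_ie) < 0:
        t_ce = -t_ce
    t_ic = _tangent(circle_ic, p)
    if t_ic @ (p - c_ce) > 0:
        t_ic = -t_ic

    psi_ie = math.atan2(t_ie[1], t_ie[0])
    psi_ic = math.atan2(t_ic[1], t_ic[0])
    psi_ce = math.atan2(t_ce[1], t_ce[0])

    theta_i = _sector(psi_ic, psi_ie, psi_ce)  # interior: between ic and ie
    theta_e = _sector(psi_ce, psi_ie, psi_ic)  # exterior: between ce and ie
    theta_c = _sector(psi_ic, psi_ce, psi_ie)  # condensate: between ic and ce
    return math.degrees(theta_i), math.degrees(theta_e), math.degrees(theta_c)


def apparent_angles(circle_ie: CircleModel, circle_ic: CircleModel,
                    circle_ce: CircleModel, contact_tol: float | None = None,
                    asymmetry_tol_deg: float = 5.0) -> ContactAngles:
    """Apparent contact angles from the three fitted interface models.

    The two contact points are the intersections of the ie (vesicle) and ce
    (condensate) circles; the ic model must pass within ``contact_tol`` of
    both (default 5% of the condensate radius).  At each contact point the
    three interface tangent rays divide the plane into the interior,
    exterior and condensate sectors; the three sector angles are measured
    at both contact points of the equatorial cross-section and averaged.
    A left/right disagreement above ``asymmetry_tol_deg`` (projection
    misalignment or poor fits) raises a GeometryError.

    The ic model may be a line (flat membrane-condensate interface); the ie
    and ce models must be circles.
    """
    if circle_ie.is_line or circle_ce.is_line:
        raise GeometryError("ie and ce interfaces must be circular arcs")
    p_a, p_b = _circle_intersections(circle_ie, circle_ce)
    if contact_tol is None:
        contact_tol = 0.05 * circle_ce.radius
    miss = np.abs(circle_ic.signed_distance(np.vstack([p_a, p_b])))
    if miss.max() > contact_tol:
        raise GeometryError(
            f"ic interface misses the contact points by {miss.max():.3g} "
            f"(tolerance {contact_tol:.3g}): inconsistent geometry")

    tri_a = _angles_at_point(p_a, circle_ie, circle_ic, circle_ce)
    tri_b = _angles_at_point(p_b, circle_ie, circle_ic, circle_ce)
    asym = max(abs(a - b) for a, b in zip(tri_a, tri_b))
    if asym > asymmetry_tol_deg:
        raise GeometryError(
            f"left/right contact-point angles disagree by {asym:.2f} deg "
            f"(tolerance {asymmetry_tol_deg}): check the projection plane")
    ti, te, tc = (0.5 * (a + b) for a, b in zip(tri_a, tri_b))
    return ContactAngles(theta_i=ti, theta_e=te, theta_c=tc, asymmetry_deg=asym)


# ---------------------------------------------------------------------------
# fluid-elastic parameters


def _sin_deg(x: float) -> float:
    return math.sin(math.radians(x))


def geometric_factor(angles: ContactAngles) -> float:
    """Geometric factor Phi = (sin theta_e - sin theta_c) / sin theta_i.

    Dimensionless material parameter in [-1, 1]; +1 at dewetting, -1 at
    complete wetting.  Undefined when theta_i is 0 or 180 degrees.
    """
    si = _sin_deg(angles.theta_i)
    if abs(si) < 1e-12:
        raise GeometryError("theta_i of 0 or 180 degrees: geometric factor undefined")
    return (_sin_deg(angles.theta_e) - _sin_deg(angles.theta_c)) / si


def intrinsic_angle(phi: float, tol: float = 1e-9) -> float:
    """Intrinsic contact angle theta_e_in = arccos(Phi), in degrees [0, 180].

    Values of ``phi`` outside [-1, 1] by at most ``tol`` (numerical noise)
    are clamped; larger excursions indicate inconsistent input geometry.
    """
    if abs(phi) > 1.0 + tol:
        raise GeometryError(f"geometric factor {phi} outside [-1, 1]: inconsistent geometry")
    return math.degrees(math.acos(min(1.0, max(-1.0, phi))))


def geometric_factor_from_intrinsic(theta_e_in_deg: float) -> float:
    """Phi = cos(theta_e_in): exact inverse of :func:`intrinsic_angle`."""
    if not (0.0 <= theta_e_in_deg <= 180.0):
        raise GeometryError("intrinsic angle must be in [0, 180] degrees")
    return math.cos(math.radians(theta_e_in_deg))


def affinity_contrast(phi: float, sigma_ce: float) -> float:
    """Affinity contrast W = Phi * Sigma_ce (units of sigma_ce, e.g. uN/m).

    W = W_ic - W_ie compares the adhesion free energies per unit area of
    the condensate-wetted and buffer-wetted membrane segments; by
    construction -Sigma_ce <= W <= +Sigma_ce.
    """
    if sigma_ce <= 0:
        raise GeometryError("sigma_ce must be > 0")
    return phi * sigma_ce


def segment_tensions(angles: ContactAngles, sigma_ce: float) -> tuple[float, float]:
    """Membrane segment tensions (Sigma_ie, Sigma_ic) from the law of sines.

    Sigma_ie = Sigma_ce sin(theta_c)/sin(theta_i);
    Sigma_ic = Sigma_ce sin(theta_e)/sin(theta_i).
    """
    if sigma_ce <= 0:
        raise GeometryError("sigma_ce must be > 0")
    si = _sin_deg(angles.theta_i)
    if abs(si) < 1e-12:
        raise GeometryError("theta_i of 0 or 180 degrees: tensions undefined")
    return (sigma_ce * _sin_deg(angles.theta_c) / si,
            sigma_ce * _sin_deg(angles.theta_e) / si)


def tension_triangle_angles(sigma_ce: float, sigma_ie: float,
                            sigma_ic: float) -> ContactAngles:
    """Apparent contact angles of a closed tension triangle.

    The three tensions form a triangle (law of cosines gives the interior
    angles); each apparent angle is 180 degrees minus the interior angle
    opposite the corresponding tension, so the triple sums to 360 degrees.
    This is the exact forward map inverted by the angle measurement.
    """
    sides = (sigma_ce, sigma_ie, sigma_ic)
    if min(sides) <= 0:
        raise GeometryError("tensions must be > 0")
    a, b, c = sides
    if a >= b + c or b >= a + c or c >= a + b:
        raise GeometryError("tension triple violates the strict triangle inequality")

    def interior(opposite: float, s1: float, s2: float) -> float:
        return math.degrees(math.acos(
            min(1.0, max(-1.0, (s1**2 + s2**2 - opposite**2) / (2.0 * s1 * s2)))))

    theta_i = 180.0 - interior(sigma_ce, sigma_ie, sigma_ic)
    theta_c = 180.0 - interior(sigma_ie, sigma_ce, sigma_ic)
    theta_e = 180.0 - interior(sigma_ic, sigma_ce, sigma_ie)
    return ContactAngles(theta_i=theta_i, theta_e=theta_e, theta_c=theta_c)


def wetting_parameters(angles: ContactAngles, sigma_ce: float) -> WettingGeometry:
    """All fluid-elastic parameters of one couple from its angle triple."""
    phi = geometric_factor(angles)
    s_ie, s_ic = segment_tensions(angles, sigma_ce)
    return WettingGeometry(
        angles=angles,
        phi=phi,
        theta_e_in=intrinsic_angle(phi, tol=0.05),  # noisy experimental phi
        sigma_ce=sigma_ce,
        affinity_contrast=affinity_contrast(phi, sigma_ce),
        sigma_ie=s_ie,
        sigma_ic=s_ic,
    )


def validate_geometry(angles: ContactAngles, sigma_ce: float = 1.0,
                      angle_sum_tol_deg: float = 1.0,
                      closure_tol: float = 1e-6) -> GeometryReport:
    """Consistency report for a measured angle triple.

    Checks the 360-degree angle sum, the [-1, 1] range of the geometric
    factor, and the closure of the tension triangle: unit tension vectors
    laid head-to-tail with exterior turns equal to the apparent angles must
    return to the start.  Violations are reported, not raised - measurement
    noise produces bounded deviations.
    """
    flags: list[str] = []
    dev = angles.angle_sum - 360.0
    sum_ok = abs(dev) <= angle_sum_tol_deg
    if not sum_ok:
        flags.append(f"angle sum deviates from 360 deg by {dev:.3f} deg")

    phi: float | None = None
    closure: float | None = None
    closure_ok = True
    try:
        phi = geometric_factor(angles)
    except GeometryError:
        flags.append("theta_i degenerate: geometric factor undefined")
    phi_ok = phi is not None and -1.0 - 1e-9 <= phi <= 1.0 + 1e-9
    if phi is not None and not phi_ok:
        flags.append(f"geometric factor {phi:.4f} outside [-1, 1]")

    if phi is not None:
        s_ie, s_ic = segment_tensions(angles, sigma_ce)
        rot_e = math.radians(angles.theta_e)
        rot_i = math.radians(angles.theta_e + angles.theta_i)
        total = (np.array([sigma_ce, 0.0])
                 + s_ie * np.array([math.cos(rot_e), math.sin(rot_e)])
                 + s_ic * np.array([math.cos(rot_i), math.sin(rot_i)]))
        closure = float(np.hypot(*total)) / sigma_ce
        closure_ok = closure <= max(closure_tol, 2.0 * math.radians(angle_sum_tol_deg))
        if not closure_ok:
            flags.append(f"tension triangle fails to close (residual {closure:.3e})")

    return GeometryReport(
        angle_sum_deg=angles.angle_sum,
        angle_sum_deviation_deg=dev,
        angle_sum_ok=sum_ok,
        phi=phi,
        phi_in_range=phi_ok,
        closure_residual=closure,
        closure_ok=closure_ok,
        flags=tuple(flags),
    )
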