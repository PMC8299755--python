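"""Virtual post-deployment repositioning of calcium deposits.

When the frame expands, native leaflet calcium is pressed outward until it
rests against the aortic wall.  Each deposit is translated along the virtual
radial line through its center until its outer face touches the wall inner
surface; irregular (rod-like) deposits additionally rotate rigidly about
their centroid until both endpoints are as close to the wall as a rigid
rotation permits.  Volume, thickness and length are conserved exactly.

The remodeled configuration drives the non-uniform displacement boundary
condition through an angular thickness profile ``d(phi)``: within each
angular sector the profile is the maximum remodeled deposit thickness (a
stack of deposits compressed by a rigid frame cannot protrude further than
its thickest member).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .fem import wrap_angle_deg
from .records import AorticRootGeometry, CalciumDeposit, cart_to_cyl, cyl_to_cart

__all__ = [
    "GeometricInfeasibilityError",
    "RemodeledDeposit",
    "displace_deposit",
    "rotate_irregular_deposit",
    "remodel_deposit",
    "remodel_all",
    "local_thickness_profile",
]

#: Endpoints count as touching the wall within this distance (mm).
CONTACT_TOL = 1e-6


class GeometricInfeasibilityError(ValueError):
    """Deposit geometry cannot be placed against the wall."""


@dataclass(frozen=True)
class RemodeledDeposit:
    """A deposit after virtual displacement (and rotation, if irregular)."""

    original: CalciumDeposit
    deposit: CalciumDeposit  # same deposit at its remodeled position
    rotation_angle: float  # degrees; 0 for regular deposits
    contacts_wall: bool

    @property
    def displaced_center(self) -> tuple[float, float, float]:
        return self.deposit.center

    @property
    def thickness(self) -> float:
        return self.deposit.thickness


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    ang = np.deg2rad(angle_deg)
    kx, ky, kz = axis
    k_cross = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return (
        np.eye(3) * np.cos(ang)
        + np.sin(ang) * k_cross
        + (1 - np.cos(ang)) * np.outer(axis, axis)
    )


def displace_deposit(
    dep: CalciumDeposit, geom: AorticRootGeometry
) -> RemodeledDeposit:
    """Shift a deposit along its radial line until it contacts the wall.

    The deposit is modeled as a slab of thickness ``d`` centered on
    ``center``; contact means the outer face reaches the wall inner surface,
    i.e. the center ends up at ``inner_radius - d / 2``.  Angular and axial
    coordinates are unchanged; endpoints (if any) translate rigidly with the
    center.
    """
    a = geom.inner_radius
    r0, phi0, z0 = dep.center
    if r0 > a + 1e-9:
        raise GeometricInfeasibilityError(
            f"deposit center radius {r0:.3f} mm lies outside the lumen ({a:.3f} mm)"
        )
    if dep.thickness > a:
        raise GeometricInfeasibilityError(
            f"deposit thickness {dep.thickness:.3f} mm exceeds lumen radius {a:.3f} mm"
        )
    r_new = a - dep.thickness / 2.0
    shift_cart = cyl_to_cart((r_new, phi0, z0)) - cyl_to_cart(dep.center)
    endpoints = None
    if dep.endpoints is not None:
        endpoints = tuple(
            cart_to_cyl(cyl_to_cart(e) + shift_cart) for e in dep.endpoints
        )
    moved = dep.moved(center=(r_new, phi0, z0), endpoints=endpoints)
    return RemodeledDeposit(
        original=dep,
        deposit=moved,
        rotation_angle=0.0,
        contacts_wall=True,
    )


def _endpoint_wall_gap(
    endpoints_cart: list[np.ndarray], center_cart: np.ndarray, rot: np.ndarray, a: float
) -> float:
    worst = 0.0
    for e in endpoints_cart:
        p = center_cart + rot @ (e - center_cart)
        worst = max(worst, abs(float(np.hypot(p[0], p[1])) - a))
    return worst


def rotate_irregular_deposit(
    dep: CalciumDeposit, geom: AorticRootGeometry
) -> RemodeledDeposit:
    """Rotate an irregular deposit so both endpoints approach the wall.

    The rotation is rigid, about the deposit centroid, around the tilt axis
    perpendicular to both the deposit's long axis and the centroid's radial
    direction.  The angle minimizes the larger of the two endpoint-to-wall
    distances; among equally good angles the smallest magnitude (then the
    positive sign) is chosen.  ``contacts_wall`` records whether both
    endpoints ended up within tolerance of the wall inner surface.
    """
    if dep.shape != "irregular" or dep.endpoints is None:
        raise ValueError("rotation applies to irregular deposits with endpoints")
    a = geom.inner_radius
    e_cart = [cyl_to_cart(e) for e in dep.endpoints]
    chord = float(np.linalg.norm(e_cart[1] - e_cart[0]))
    if chord > 2.0 * a:
        raise GeometricInfeasibilityError(
            f"endpoint chord {chord:.3f} mm exceeds lumen diameter {2 * a:.3f} mm"
        )
    c_cart = cyl_to_cart(dep.center)
    radial = np.array([c_cart[0], c_cart[1], 0.0])
    if np.linalg.norm(radial) < 1e-12:
        radial = np.array([1.0, 0.0, 0.0])
    radial /= np.linalg.norm(radial)
    long_axis = e_cart[1] - e_cart[0]
    axis = np.cross(long_axis, radial)
    if np.linalg.norm(axis) < 1e-12:
        # rod already radial: tilt about the tangential direction
        axis = np.cross(np.array([0.0, 0.0, 1.0]), radial)
    axis /= np.linalg.norm(axis)

    def objective(angle: float) -> float:
        return _endpoint_wall_gap(e_cart, c_cart, _rotation_matrix(axis, angle), a)

    def objective_grid(angles: np.ndarray) -> np.ndarray:
        # Rodrigues rotation of both endpoints, vectorized over angles
        ang = np.deg2rad(angles)[:, None]
        cos_a, sin_a = np.cos(ang), np.sin(ang)
        worst = np.zeros(angles.size)
        for e in e_cart:
            v = e - c_cart
            rotated = (
                cos_a * v
                + sin_a * np.cross(axis, v)
                + (1.0 - cos_a) * np.dot(axis, v) * axis
            ) + c_cart
            rho = np.hypot(rotated[:, 0], rotated[:, 1])
            worst = np.maximum(worst, np.abs(rho - a))
        return worst

    grid = np.arange(-180.0, 180.0, 0.25)
    vals = objective_grid(grid)
    best = vals.min()
    # among near-optimal coarse cells prefer the smallest |angle|, then positive
    near = grid[vals <= best + 1e-9]
    start = near[np.lexsort((near < 0, np.abs(near)))][0]
    res = minimize_scalar(
        objective, bounds=(start - 0.5, start + 0.5), method="bounded",
        options={"xatol": 1e-10},
    )
    angle = float(res.x)
    if objective(0.0) <= objective(angle) + CONTACT_TOL * 1e-3:
        angle = 0.0
    rot = _rotation_matrix(axis, angle)
    new_endpoints = tuple(
        cart_to_cyl(c_cart + rot @ (e - c_cart)) for e in e_cart
    )
    contact = objective(angle) <= CONTACT_TOL
    moved = dep.moved(center=dep.center, endpoints=new_endpoints)
    return RemodeledDeposit(
        original=dep,
        deposit=moved,
        rotation_angle=angle,
        contacts_wall=contact,
    )


def remodel_deposit(dep: CalciumDeposit, geom: AorticRootGeometry) -> RemodeledDeposit:
    """Full virtual remodeling: radial displacement, then rotation if irregular."""
    displaced = displace_deposit(dep, geom)
    if dep.shape == "regular":
        return displaced
    rotated = rotate_irregular_deposit(displaced.deposit, geom)
    return RemodeledDeposit(
        original=dep,
        deposit=rotated.deposit,
        rotation_angle=rotated.rotation_angle,
        contacts_wall=rotated.contacts_wall,
    )


def remodel_all(
    deposits: list[CalciumDeposit], geom: AorticRootGeometry
) -> list[RemodeledDeposit]:
    return [remodel_deposit(d, geom) for d in deposits]


def local_thickness_profile(
    deposits: list[RemodeledDeposit],
    geom: AorticRootGeometry,
    n_sectors: int,
) -> np.ndarray:
    """Per-sector calcium thickness profile d(phi) after remodeling.

    Sector ``j`` covers ``[j * 360 / n_sectors, (j + 1) * 360 / n_sectors)``.
    A sector's value is the maximum thickness among deposits overlapping it
    (0 where none); overlap is tested between the sector interval and the
    deposit's angular footprint on the wall.
    """
    if n_sectors < 4:
        raise ValueError(f"need at least 4 sectors, got {n_sectors}")
    width = 360.0 / n_sectors
    sector_centers = (np.arange(n_sectors) + 0.5) * width
    profile = np.zeros(n_sectors)
    a = geom.inner_radius
    for rd in deposits:
        dep = rd.deposit
        _, phi_c, _ = dep.center
        if dep.endpoints is not None:
            spans = [
                abs(wrap_angle_deg(e[1] - phi_c)) for e in dep.endpoints
            ]
            half = max(float(max(spans)), 1e-9)
        else:
            half = float(np.rad2deg(np.arcsin(min(1.0, dep.length / 2.0 / a))))
        dist = np.abs(wrap_angle_deg(sector_centers - phi_c))
        hit = dist < half + width / 2.0
        profile[hit] = np.maximum(profile[hit], dep.thickness)
    return profile
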