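"""Tissue material constants, volumetric homogenization, and the scalar loading-force law.

After deployment the native leaflets are pressed against the aortic root, so
the annulus tissue behaves as a volume-weighted mixture of root and leaflet
material.  The mixture rule is a plain convex combination driven by the root
volume fraction ``p_root``; the same rule is applied to Young's modulus,
Poisson's ratio and density.

The loading force exerted by a fully expanded self-expanding frame is modeled
geometrically: ``F = K * (R - C_annu / (2 pi) + d)`` where ``K`` (N/mm) is the
radial stiffness of the aortic wall, ``R`` (mm) the prosthesis radius,
``C_annu`` (mm) the annulus circumference and ``d`` (mm) the interposed
calcium thickness.  ``R`` is taken as half the nominal device size: nominal
sizes (23/26/29/31 mm) are diameters, while ``C_annu / (2 pi)`` is a radius,
so the difference is only dimensionally meaningful between radii.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MaterialParams",
    "AORTIC_ROOT",
    "AORTIC_VALVE",
    "LoadingForce",
    "homogenize",
    "loading_force",
]


@dataclass(frozen=True)
class MaterialParams:
    """Isotropic linear-elastic material constants.

    Attributes
    ----------
    youngs_modulus : float
        Young's modulus E, MPa.
    poisson_ratio : float
        Poisson's ratio, dimensionless, in (0, 0.5).
    density : float
        Mass density, kg/m^3.
    """

    youngs_modulus: float
    poisson_ratio: float
    density: float

    def __post_init__(self) -> None:
        if not self.youngs_modulus > 0:
            raise ValueError(f"Young's modulus must be positive, got {self.youngs_modulus}")
        if not (0.0 < self.poisson_ratio < 0.5):
            raise ValueError(
                f"Poisson's ratio must lie in (0, 0.5), got {self.poisson_ratio}"
            )
        if not self.density > 0:
            raise ValueError(f"density must be positive, got {self.density}")

    @property
    def lame_lambda(self) -> float:
        """First Lame parameter, MPa."""
        e, nu = self.youngs_modulus, self.poisson_ratio
        return e * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))

    @property
    def lame_mu(self) -> float:
        """Shear modulus, MPa."""
        return self.youngs_modulus / (2.0 * (1.0 + self.poisson_ratio))


#: Aortic root wall tissue.
AORTIC_ROOT = MaterialParams(youngs_modulus=2.0, poisson_ratio=0.45, density=2000.0)

#: Native (calcified) aortic valve leaflet tissue.
AORTIC_VALVE = MaterialParams(youngs_modulus=8.0, poisson_ratio=0.45, density=1100.0)


def homogenize(root: MaterialParams, valve: MaterialParams, p_root: float) -> MaterialParams:
    """Volume-weighted homogenization of root and leaflet tissue.

    Parameters
    ----------
    root, valve : MaterialParams
        Endpoint materials.
    p_root : float
        Volumetric fraction of aortic-root tissue, in [0, 1].

    Returns
    -------
    MaterialParams
        Convex combination ``valve * (1 - p_root) + root * p_root`` applied
        field by field.
    """
    if not (0.0 <= p_root <= 1.0):
        raise ValueError(f"p_root must lie in [0, 1], got {p_root}")
    w = float(p_root)
    return MaterialParams(
        youngs_modulus=valve.youngs_modulus * (1.0 - w) + root.youngs_modulus * w,
        poisson_ratio=valve.poisson_ratio * (1.0 - w) + root.poisson_ratio * w,
        density=valve.density * (1.0 - w) + root.density * w,
    )


@dataclass(frozen=True)
class LoadingForce:
    """Scalar radial loading force of a deployed frame and its components.

    ``force = stiffness * (valve_radius - annulus_radius + calcium_thickness)``
    holds exactly.  A negative force means the chosen device undersizes the
    annulus (no interference fit); it is returned as-is and flagged.
    """

    force: float  # N
    stiffness: float  # N/mm
    valve_radius: float  # mm
    annulus_radius: float  # mm
    calcium_thickness: float  # mm

    @property
    def undersized(self) -> bool:
        return self.force < 0.0


def loading_force(
    stiffness: float,
    valve_size: float,
    annulus_circumference: float,
    calcium_thickness: float,
) -> LoadingForce:
    """Loading force of a fully expanded frame against the annulus.

    Parameters
    ----------
    stiffness : float
        Radial stiffness K of the aortic wall, N/mm.
    valve_size : float
        Nominal device size (diameter), mm.
    annulus_circumference : float
        Native annulus circumference, mm.
    calcium_thickness : float
        Interposed calcium thickness d, mm (>= 0).
    """
    if not stiffness > 0:
        raise ValueError(f"wall stiffness must be positive, got {stiffness}")
    if not annulus_circumference > 0:
        raise ValueError(
            f"annulus circumference must be positive, got {annulus_circumference}"
        )
    if calcium_thickness < 0:
        raise ValueError(f"calcium thickness must be >= 0, got {calcium_thickness}")
    r_valve = valve_size / 2.0
    r_annulus = annulus_circumference / (2.0 * np.pi)
    f = stiffness * (r_valve - r_annulus + calcium_thickness)
    return LoadingForce(
        force=f,
        stiffness=stiffness,
        valve_radius=r_valve,
        annulus_radius=r_annulus,
        calcium_thickness=calcium_thickness,
    )
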