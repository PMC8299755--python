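"""Domain records: aortic-root geometry, calcium deposits, patient records.

Cylindrical coordinates ``(r, phi, z)`` are used throughout: radius in mm,
``phi`` in degrees in [0, 360) with 0 at the NCC-RCC commissure midpoint
(conduction-zone center), ``z`` in mm above the annulus plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AorticRootGeometry",
    "CalciumDeposit",
    "PatientRecord",
    "CUSPS",
    "cyl_to_cart",
    "cart_to_cyl",
]

CUSPS = ("NCC", "RCC", "LCC")


def cyl_to_cart(point: tuple[float, float, float]) -> np.ndarray:
    """(r, phi_deg, z) -> cartesian (x, y, z)."""
    r, phi, z = point
    phi_rad = np.deg2rad(phi)
    return np.array([r * np.cos(phi_rad), r * np.sin(phi_rad), z])


def cart_to_cyl(xyz: np.ndarray) -> tuple[float, float, float]:
    """Cartesian (x, y, z) -> (r, phi_deg in [0, 360), z)."""
    x, y, z = xyz
    r = float(np.hypot(x, y))
    phi = float(np.rad2deg(np.arctan2(y, x))) % 360.0
    return (r, phi, float(z))


@dataclass(frozen=True)
class AorticRootGeometry:
    """Patient-level annulus geometry and wall properties.

    Attributes
    ----------
    annulus_circumference : float
        Native annulus circumference C, mm.
    wall_thickness : float
        Aortic wall thickness, mm.
    annulus_height : float
        Axial extent of the modeled landing zone, mm.
    wall_stiffness : float
        Radial wall stiffness K, N/mm (from force-displacement regression).
    root_volume, leaflet_volume : float
        Tissue volumes, mm^3; their ratio sets the homogenization fraction.
    commissure_angle_ncc_rcc : float
        Angular location of the NCC-RCC commissure midpoint; 0 by the shared
        convention (all angles are measured from it).
    """

    annulus_circumference: float
    wall_thickness: float
    annulus_height: float
    wall_stiffness: float
    root_volume: float
    leaflet_volume: float
    commissure_angle_ncc_rcc: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "annulus_circumference",
            "wall_thickness",
            "annulus_height",
            "wall_stiffness",
            "root_volume",
            "leaflet_volume",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def inner_radius(self) -> float:
        """Annulus (lumen) radius C / 2 pi, mm."""
        return self.annulus_circumference / (2.0 * np.pi)

    @property
    def p_root(self) -> float:
        """Volumetric fraction of root tissue used for homogenization."""
        return self.root_volume / (self.root_volume + self.leaflet_volume)


@dataclass(frozen=True)
class CalciumDeposit:
    """One leaflet calcium deposit.

    Regular deposits are slabs of thickness ``thickness`` whose radial
    position is given by ``center``.  Irregular deposits additionally carry
    two endpoints spanning the deposit's long axis; they rotate during
    remodeling until the ends rest against the wall.
    """

    center: tuple[float, float, float]  # (r mm, phi deg, z mm)
    thickness: float  # mm
    length: float  # mm
    volume: float  # mm^3
    cusp: str  # NCC | RCC | LCC
    shape: str = "regular"  # regular | irregular
    endpoints: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"deposit thickness must be positive, got {self.thickness}")
        if self.volume <= 0:
            raise ValueError(f"deposit volume must be positive, got {self.volume}")
        if self.length <= 0:
            raise ValueError(f"deposit length must be positive, got {self.length}")
        if self.cusp not in CUSPS:
            raise ValueError(f"cusp must be one of {CUSPS}, got {self.cusp!r}")
        if self.shape not in ("regular", "irregular"):
            raise ValueError(f"shape must be regular or irregular, got {self.shape!r}")
        if (self.endpoints is not None) != (self.shape == "irregular"):
            raise ValueError("endpoints must be present iff shape is irregular")

    def moved(self, center, endpoints=None) -> "CalciumDeposit":
        """Copy with new position; thickness/length/volume are conserved."""
        return replace(self, center=center, endpoints=endpoints)


@dataclass
class PatientRecord:
    """One synthetic patient: demographics, comorbidities, geometry, calcium."""

    id: int
    sex: str  # "male" | "female"
    age: float  # years
    bmi: float  # kg/m^2
    systolic_bp: float  # mmHg
    diastolic_bp: float  # mmHg
    lvef: float  # percent
    diabetes: bool
    afib_history: bool
    stroke_history: bool
    icb_history: bool
    geometry: AorticRootGeometry
    deposits: list[CalciumDeposit] = field(default_factory=list)
    avb_label: int = 0
    applied_valve_size: float = 26.0

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male or female, got {self.sex!r}")
        if self.avb_label not in (0, 1):
            raise ValueError(f"avb_label must be 0 or 1, got {self.avb_label}")

    @property
    def calcified_volume(self) -> float:
        """Total calcified volume V, mm^3 (sum over deposits)."""
        return float(sum(d.volume for d in self.deposits))
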