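"""Forward biomechanical pipeline for one patient.

Chains the standard stages: homogenize tissue properties, remodel the calcium
deposits against the wall, turn them into an angular thickness profile, build
the displacement boundary condition for a candidate prosthesis, solve the
elastic deployment problem, and read off the conduction-zone stress features.

``ForwardModel`` caches everything that does not depend on the candidate
valve (mesh, remodeled deposits, stiffness factorizations), so design-space
sweeps over (size, theta) are cheap.
"""

from __future__ import annotations

import numpy as np

from . import fem
from .materials import AORTIC_ROOT, AORTIC_VALVE, MaterialParams, homogenize
from .records import AorticRootGeometry, CalciumDeposit
from .remodel import local_thickness_profile, remodel_all
from .valves import ValveDesign

__all__ = ["patient_material", "ForwardModel"]


def patient_material(
    geom: AorticRootGeometry,
    root: MaterialParams = AORTIC_ROOT,
    valve: MaterialParams = AORTIC_VALVE,
) -> MaterialParams:
    """Homogenized annulus tissue for a patient (root/leaflet volume mix)."""
    return homogenize(root, valve, geom.p_root)


class ForwardModel:
    """Deployment-stress evaluator for one patient at a fixed resolution."""

    def __init__(
        self,
        geometry: AorticRootGeometry,
        deposits: list[CalciumDeposit],
        resolution: tuple[int, int, int] = fem.DEFAULT_RESOLUTION,
        band_height: float = 4.0,
        half_angle_deg: float = 45.0,
        root_material: MaterialParams = AORTIC_ROOT,
        valve_material: MaterialParams = AORTIC_VALVE,
        material: MaterialParams | None = None,
    ):
        self.geometry = geometry
        self.resolution = resolution
        self.band_height = band_height
        self.half_angle_deg = half_angle_deg
        self.material = material or patient_material(
            geometry, root_material, valve_material
        )
        self.mesh = fem.build_annulus_mesh(geometry, resolution)
        self.remodeled = remodel_all(deposits, geometry)
        # align the thickness profile with the mesh's circumferential columns
        self.d_profile = local_thickness_profile(
            self.remodeled, geometry, n_sectors=resolution[0]
        )
        self.system = fem.ElasticSystem(self.mesh, self.material)

    @property
    def max_remodeled_thickness(self) -> float:
        return max((rd.thickness for rd in self.remodeled), default=0.0)

    @property
    def feature_node_ids(self) -> np.ndarray:
        return fem.conduction_zone_node_ids(
            self.mesh, self.band_height, self.half_angle_deg
        )

    def boundary_condition(self, valve: ValveDesign) -> fem.BoundaryCondition:
        return fem.make_boundary_condition(
            self.mesh, self.geometry, valve, self.d_profile
        )

    def solve(self, valve: ValveDesign) -> fem.StressField:
        return self.system.solve(self.boundary_condition(valve))

    def features(self, valve: ValveDesign) -> np.ndarray:
        """Conduction-zone von Mises stress vector for a candidate valve."""
        return fem.conduction_zone_features(
            self.solve(valve), self.mesh, self.band_height, self.half_angle_deg
        )

    def summary(self, valve: ValveDesign) -> float:
        """Tributary-area-weighted mean conduction-zone stress, MPa."""
        ids = self.feature_node_ids
        field = self.solve(valve)
        w = self.mesh.tributary_area[ids]
        return float(np.average(field.von_mises[ids], weights=w))

    def unit_uniform_response(self) -> np.ndarray:
        """Feature response to 1 mm of uniform inner-surface displacement.

        Uses the complete-frame (theta = 0) constraint pattern, so the cached
        factorization of training solves is reused.  By linearity, the feature
        change for an extra uniform oversize ``delta`` is ``delta`` times this
        vector.
        """
        # oversize works out to exactly 1 mm of uniform radial displacement
        bc = fem.make_boundary_condition(
            self.mesh,
            self.geometry,
            ValveDesign(size=2.0 * self.geometry.inner_radius + 2.0, theta_deg=0.0),
            d_profile=None,
        )
        field = self.system.solve(bc)
        return fem.conduction_zone_features(
            field, self.mesh, self.band_height, self.half_angle_deg
        )
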