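"""Structured hexahedral annulus mesh and small-strain linear elasticity solver.

The computational domain is the aortic annulus wall, modeled as a thick
cylindrical shell meshed with trilinear hexahedra (hex8).  Stent deployment is
imposed as a displacement boundary condition on the inner (lumen) surface:
every inner-surface node is pushed radially outward by the frame oversize plus
the local calcium thickness, except for nodes inside the vacancy sector of the
frame, which remain unloaded.  The static equilibrium of the isotropic Hooke
solid is then solved for the free nodes and von Mises stress is recovered at
the nodes.

Conventions shared across the package:

* lengths in mm, moduli in MPa, forces in N;
* angle ``phi`` in degrees, measured counterclockwise (viewed from the aorta)
  with 0 deg at the midpoint of the NCC-RCC commissure, i.e. at the center of
  the conduction-system zone;
* node ordering is phi-major, then axial, then radial, so feature vectors
  align across patients meshed at the same resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .materials import MaterialParams
from .valves import ValveDesign

__all__ = [
    "DEFAULT_RESOLUTION",
    "HexMesh",
    "BoundaryCondition",
    "StressField",
    "RigidModeError",
    "build_annulus_mesh",
    "make_boundary_condition",
    "ElasticSystem",
    "solve_stress",
    "conduction_zone_node_ids",
    "conduction_zone_features",
    "wrap_angle_deg",
]

#: Default (n_circ, n_axial, n_radial) resolution triple.  The product is the
#: element count of the shipped annulus model: 92 * 17 * 5 = 7820 hexahedra.
DEFAULT_RESOLUTION: tuple[int, int, int] = (92, 17, 5)

# Hex8 reference-element corner signs, local axes (xi, eta, zeta) mapped to
# (circumferential, axial, radial).  This ordering gives a positive Jacobian.
_CORNER_SIGNS = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)

_GAUSS = np.array(
    [[sx / np.sqrt(3.0), sy / np.sqrt(3.0), sz / np.sqrt(3.0)]
     for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
    dtype=float,
)


class RigidModeError(RuntimeError):
    """Raised when the constrained system still admits rigid-body motion."""


def wrap_angle_deg(phi: np.ndarray | float) -> np.ndarray | float:
    """Map angles in degrees to the interval (-180, 180]."""
    return -(-(np.asarray(phi) - 180.0) % 360.0) + 180.0


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """d N_a / d xi_j at a reference point, shape (8, 3)."""
    s = _CORNER_SIGNS
    g = np.empty((8, 3))
    g[:, 0] = 0.125 * s[:, 0] * (1 + s[:, 1] * xi[1]) * (1 + s[:, 2] * xi[2])
    g[:, 1] = 0.125 * s[:, 1] * (1 + s[:, 0] * xi[0]) * (1 + s[:, 2] * xi[2])
    g[:, 2] = 0.125 * s[:, 2] * (1 + s[:, 0] * xi[0]) * (1 + s[:, 1] * xi[1])
    return g


@dataclass
class HexMesh:
    """Structured, circumferentially periodic hex8 mesh of the annulus wall."""

    node_coords: np.ndarray  # (n_nodes, 3) mm
    elements: np.ndarray  # (n_elements, 8) node ids
    resolution: tuple[int, int, int]
    inner_radius: float  # mm
    wall_thickness: float  # mm
    height: float  # mm
    node_r: np.ndarray = field(repr=False, default=None)
    node_phi_deg: np.ndarray = field(repr=False, default=None)  # in [0, 360)
    node_z: np.ndarray = field(repr=False, default=None)
    node_ir: np.ndarray = field(repr=False, default=None)
    node_iz: np.ndarray = field(repr=False, default=None)

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def boundary_node_ids(self) -> np.ndarray:
        """Inner-surface nodes: repositioned directly by the expanding frame."""
        return np.flatnonzero(self.node_ir == 0)

    @property
    def free_node_ids(self) -> np.ndarray:
        return np.flatnonzero(self.node_ir != 0)

    @property
    def tributary_area(self) -> np.ndarray:
        """Inner-surface area (mm^2) attributed to each node (0 off-surface)."""
        n_circ, n_axial, _ = self.resolution
        patch = (2.0 * np.pi * self.inner_radius / n_circ) * (self.height / n_axial)
        area = np.zeros(self.n_nodes)
        inner = self.node_ir == 0
        area[inner] = patch
        ends = inner & ((self.node_iz == 0) | (self.node_iz == n_axial))
        area[ends] = 0.5 * patch
        return area


def build_annulus_mesh(
    geom, resolution: tuple[int, int, int] = DEFAULT_RESOLUTION
) -> HexMesh:
    """Build the periodic structured cylinder-shell mesh of the annulus.

    Parameters
    ----------
    geom : AorticRootGeometry
        Supplies inner radius, wall thickness and annulus height.
    resolution : (n_circ, n_axial, n_radial)
        Elements along each direction.  The default reproduces the shipped
        7820-element annulus model.
    """
    n_circ, n_axial, n_radial = resolution
    if n_circ < 4 or n_axial < 1 or n_radial < 1:
        raise ValueError(f"resolution too coarse: {resolution}")
    if not geom.wall_thickness > 0:
        raise ValueError(f"wall thickness must be positive, got {geom.wall_thickness}")
    if not geom.annulus_height > 0:
        raise ValueError(f"annulus height must be positive, got {geom.annulus_height}")
    a = geom.inner_radius
    t = geom.wall_thickness
    h = geom.annulus_height

    n_z = n_axial + 1
    n_r = n_radial + 1
    iphi, iz, ir = np.meshgrid(
        np.arange(n_circ), np.arange(n_z), np.arange(n_r), indexing="ij"
    )
    iphi, iz, ir = iphi.ravel(), iz.ravel(), ir.ravel()
    phi = iphi * (360.0 / n_circ)
    r = a + ir * (t / n_radial)
    z = iz * (h / n_axial)
    phi_rad = np.deg2rad(phi)
    coords = np.column_stack([r * np.cos(phi_rad), r * np.sin(phi_rad), z])

    def nid(ip, jz, kr):
        return (ip % n_circ) * (n_z * n_r) + jz * n_r + kr

    ip, jz, kr = np.meshgrid(
        np.arange(n_circ), np.arange(n_axial), np.arange(n_radial), indexing="ij"
    )
    ip, jz, kr = ip.ravel(), jz.ravel(), kr.ravel()
    # local corners in (phi, z, r) offsets matching _CORNER_SIGNS
    offsets = ((_CORNER_SIGNS + 1) / 2).astype(int)
    elems = np.stack(
        [nid(ip + o[0], jz + o[1], kr + o[2]) for o in offsets], axis=1
    )
    return HexMesh(
        node_coords=coords,
        elements=elems,
        resolution=(n_circ, n_axial, n_radial),
        inner_radius=a,
        wall_thickness=t,
        height=h,
        node_r=r,
        node_phi_deg=phi,
        node_z=z,
        node_ir=ir,
        node_iz=iz,
    )


@dataclass
class BoundaryCondition:
    """Dirichlet data for a stent-deployment solve.

    ``dirichlet`` maps global dof index (3 * node + component) to the
    prescribed displacement value in mm.  ``u_radial`` records the prescribed
    outward radial displacement per inner-surface node (NaN inside the vacancy
    sector, where the frame exerts no contact).
    """

    dirichlet: dict[int, float]
    theta_deg: float
    u_radial: np.ndarray
    vacant_node_ids: np.ndarray

    def scaled(self, factor: float) -> "BoundaryCondition":
        """Same constraint pattern with all prescribed values scaled."""
        return BoundaryCondition(
            dirichlet={k: v * factor for k, v in self.dirichlet.items()},
            theta_deg=self.theta_deg,
            u_radial=self.u_radial * factor,
            vacant_node_ids=self.vacant_node_ids,
        )


def make_boundary_condition(
    mesh: HexMesh,
    geom,
    valve: ValveDesign,
    d_profile: np.ndarray | None = None,
    axial_constraint: str = "ends",
) -> BoundaryCondition:
    """Displacement boundary condition for a deployed frame.

    Inner-surface nodes outside the vacancy sector are displaced radially by
    ``max(0, valve_radius - annulus_radius) + d(phi)`` where ``d(phi)`` is the
    per-sector remodeled calcium thickness profile; their tangential and axial
    components are clamped (the frame grips the wall).  Nodes inside the
    vacancy sector ``(-theta/2, theta/2)`` carry no prescription.

    ``axial_constraint`` is ``"ends"`` (clamp u_z on the two axial end faces,
    removing rigid modes) or ``"full"`` (clamp u_z everywhere, enforcing
    plane-strain kinematics; used when comparing against the plane-strain
    closed form).
    """
    theta = valve.theta_deg
    if not (0.0 <= theta < 360.0):
        raise ValueError(f"vacancy angle must lie in [0, 360), got {theta}")
    if axial_constraint not in ("ends", "full"):
        raise ValueError(f"unknown axial_constraint {axial_constraint!r}")
    oversize = max(0.0, valve.size / 2.0 - geom.inner_radius)

    inner = mesh.boundary_node_ids
    phi = mesh.node_phi_deg[inner]
    if d_profile is None:
        d_local = np.zeros(inner.size)
    else:
        d_profile = np.asarray(d_profile, dtype=float)
        n_sectors = d_profile.size
        sector = (np.floor(phi / (360.0 / n_sectors)).astype(int)) % n_sectors
        d_local = d_profile[sector]

    vacant = np.abs(wrap_angle_deg(phi)) < theta / 2.0
    u_r = np.where(vacant, np.nan, oversize + d_local)

    dirichlet: dict[int, float] = {}
    phi_rad = np.deg2rad(phi)
    for k, node in enumerate(inner):
        if vacant[k]:
            continue
        ur = u_r[k]
        dirichlet[3 * node + 0] = ur * float(np.cos(phi_rad[k]))
        dirichlet[3 * node + 1] = ur * float(np.sin(phi_rad[k]))
        dirichlet[3 * node + 2] = 0.0

    n_axial = mesh.resolution[1]
    if axial_constraint == "full":
        z_nodes = np.arange(mesh.n_nodes)
    else:
        z_nodes = np.flatnonzero((mesh.node_iz == 0) | (mesh.node_iz == n_axial))
    for node in z_nodes:
        dirichlet.setdefault(3 * int(node) + 2, 0.0)

    return BoundaryCondition(
        dirichlet=dirichlet,
        theta_deg=theta,
        u_radial=u_r,
        vacant_node_ids=inner[vacant],
    )


@dataclass
class StressField:
    """Solution of one deployment solve."""

    displacement: np.ndarray  # (n_nodes, 3) mm
    stress_voigt: np.ndarray  # (n_nodes, 6) MPa, order xx yy zz xy yz zx
    von_mises: np.ndarray  # (n_nodes,) MPa
    residual: float  # relative residual of the reduced linear system


def _von_mises(voigt: np.ndarray) -> np.ndarray:
    sxx, syy, szz, sxy, syz, szx = voigt.T
    return np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
        + 3.0 * (sxy**2 + syz**2 + szx**2)
    )


class ElasticSystem:
    """Assembled stiffness operator for one mesh + material.

    Assembly happens once; LU factorizations of the reduced system are cached
    per constraint pattern, so sweeps over valve sizes at a fixed vacancy angle
    reuse the factorization and only re-solve the right-hand side.
    """

    def __init__(self, mesh: HexMesh, material: MaterialParams):
        self.mesh = mesh
        self.material = material
        self._factor_cache: dict[frozenset, tuple] = {}
        self._assemble()

    def _assemble(self) -> None:
        mesh, mat = self.mesh, self.material
        lam, mu = mat.lame_lambda, mat.lame_mu
        X = mesh.node_coords[mesh.elements]  # (m, 8, 3)
        m = mesh.n_elements
        # isotropic Hooke matrix, Voigt order xx yy zz xy yz zx (eng. shear)
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] = lam + 2.0 * mu
        D[np.arange(3, 6), np.arange(3, 6)] = mu
        ke = np.zeros((m, 24, 24))
        B = np.zeros((m, 6, 24))
        grads = []
        for g in range(8):
            dndxi = _shape_gradients(_GAUSS[g])  # (8, 3)
            jac = np.einsum("aj,mak->mjk", dndxi, X)  # (m, 3, 3)
            det = np.linalg.det(jac)
            if np.any(det <= 0):
                raise ValueError("non-positive Jacobian in annulus mesh")
            jinv = np.linalg.inv(jac)
            gradn = np.einsum("aj,mkj->mak", dndxi, jinv)  # dN_a/dx_k
            grads.append(gradn)
            B[:] = 0.0
            cols = np.arange(8) * 3
            B[:, 0, cols + 0] = gradn[:, :, 0]
            B[:, 1, cols + 1] = gradn[:, :, 1]
            B[:, 2, cols + 2] = gradn[:, :, 2]
            B[:, 3, cols + 0] = gradn[:, :, 1]
            B[:, 3, cols + 1] = gradn[:, :, 0]
            B[:, 4, cols + 1] = gradn[:, :, 2]
            B[:, 4, cols + 2] = gradn[:, :, 1]
            B[:, 5, cols + 0] = gradn[:, :, 2]
            B[:, 5, cols + 2] = gradn[:, :, 0]
            db = np.matmul(D[None, :, :], B)
            ke += det[:, None, None] * np.matmul(B.transpose(0, 2, 1), db)
        self._gauss_grads = grads
        edof = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(m, 24)
        rows = np.repeat(edof, 24, axis=1).ravel()
        cols = np.tile(edof, (1, 24)).ravel()
        ndof = 3 * mesh.n_nodes
        self.stiffness = sp.coo_matrix(
            (ke.ravel(), (rows, cols)), shape=(ndof, ndof)
        ).tocsr()

    def solve_displacement(self, dirichlet: dict[int, float]) -> tuple[np.ndarray, float]:
        """Solve static equilibrium under Dirichlet data; returns (u, residual)."""
        ndof = 3 * self.mesh.n_nodes
        if not dirichlet:
            raise RigidModeError("no constraints: system is singular")
        cons = np.fromiter(dirichlet.keys(), dtype=int)
        vals = np.fromiter((dirichlet[c] for c in cons), dtype=float)
        order = np.argsort(cons)
        cons, vals = cons[order], vals[order]
        key = frozenset(cons.tolist())
        if key in self._factor_cache:
            free, lu = self._factor_cache[key]
        else:
            mask = np.ones(ndof, dtype=bool)
            mask[cons] = False
            free = np.flatnonzero(mask)
            kff = self.stiffness[free][:, free].tocsc()
            try:
                # symmetric positive-definite system: MMD on A^T + A is much
                # cheaper than the default COLAMD here
                lu = splu(kff, permc_spec="MMD_AT_PLUS_A")
            except RuntimeError as exc:  # singular factorization
                raise RigidModeError(
                    "reduced stiffness is singular; add constraints"
                ) from exc
            self._factor_cache[key] = (free, lu)
        u = np.zeros(ndof)
        u[cons] = vals
        rhs = -self.stiffness[free][:, cons] @ vals
        uf = lu.solve(rhs)
        res = np.linalg.norm(self.stiffness[free][:, free] @ uf - rhs)
        scale = np.linalg.norm(rhs)
        residual = res / scale if scale > 0 else res
        if not np.all(np.isfinite(uf)):
            raise RigidModeError("solver produced non-finite displacements")
        u[free] = uf
        return u.reshape(-1, 3), float(residual)

    def stress_field(self, displacement: np.ndarray, residual: float = 0.0) -> StressField:
        """Recover nodal stresses by quadrature-point averaging."""
        mesh, mat = self.mesh, self.material
        lam, mu = mat.lame_lambda, mat.lame_mu
        U = displacement[mesh.elements]  # (m, 8, 3)
        m = mesh.n_elements
        elem_stress = np.zeros((m, 3, 3))
        for gradn in self._gauss_grads:
            gradu = np.einsum("mai,maj->mij", gradn, U)  # d u_j / d x_i
            eps = 0.5 * (gradu + gradu.transpose(0, 2, 1))
            trace = np.einsum("mii->m", eps)
            elem_stress += 2.0 * mu * eps
            elem_stress += lam * trace[:, None, None] * np.eye(3)[None]
        elem_stress /= 8.0
        voigt_e = np.stack(
            [
                elem_stress[:, 0, 0],
                elem_stress[:, 1, 1],
                elem_stress[:, 2, 2],
                elem_stress[:, 0, 1],
                elem_stress[:, 1, 2],
                elem_stress[:, 2, 0],
            ],
            axis=1,
        )
        nodal = np.zeros((mesh.n_nodes, 6))
        counts = np.zeros(mesh.n_nodes)
        np.add.at(nodal, mesh.elements.ravel(), np.repeat(voigt_e, 8, axis=0))
        np.add.at(counts, mesh.elements.ravel(), 1.0)
        nodal /= counts[:, None]
        return StressField(
            displacement=displacement,
            stress_voigt=nodal,
            von_mises=_von_mises(nodal),
            residual=residual,
        )

    def solve(self, bc: BoundaryCondition) -> StressField:
        u, res = self.solve_displacement(bc.dirichlet)
        return self.stress_field(u, res)


def solve_stress(mesh: HexMesh, material: MaterialParams, bc: BoundaryCondition) -> StressField:
    """One-shot deployment solve (assemble, factorize, solve, recover)."""
    return ElasticSystem(mesh, material).solve(bc)


def radial_reaction(system: "ElasticSystem", displacement: np.ndarray) -> float:
    """Total outward radial contact force (N) on the inner surface.

    Computed from the assembled operator as the radial projection of the
    nodal reaction forces over the inner-surface nodes.
    """
    mesh = system.mesh
    r_full = (system.stiffness @ displacement.ravel()).reshape(-1, 3)
    inner = mesh.boundary_node_ids
    phi = np.deg2rad(mesh.node_phi_deg[inner])
    return float(
        np.sum(r_full[inner, 0] * np.cos(phi) + r_full[inner, 1] * np.sin(phi))
    )


def conduction_zone_node_ids(
    mesh: HexMesh, band_height: float = 4.0, half_angle_deg: float = 45.0
) -> np.ndarray:
    """Inner-surface nodes inside the conduction-system zone.

    The zone is the interleaflet triangle between NCC and RCC: an angular
    sector of ``2 * half_angle_deg`` (default 90 deg) centered on 0 deg,
    intersected with the axial band ``z <= band_height`` above the annulus
    plane.  Ordering is by global node id, hence deterministic.
    """
    inner = mesh.boundary_node_ids
    phi_ok = np.abs(wrap_angle_deg(mesh.node_phi_deg[inner])) < half_angle_deg
    z_ok = mesh.node_z[inner] <= band_height + 1e-9
    ids = inner[phi_ok & z_ok]
    if ids.size == 0:
        raise ValueError("conduction zone is empty: degenerate band or sector")
    return ids


def conduction_zone_features(
    field: StressField,
    mesh: HexMesh,
    band_height: float = 4.0,
    half_angle_deg: float = 45.0,
) -> np.ndarray:
    """Ordered von Mises stress vector (MPa) over the conduction-zone nodes."""
    ids = conduction_zone_node_ids(mesh, band_height, half_angle_deg)
    return field.von_mises[ids].copy()
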