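"""Annulus mesh construction, boundary conditions, and the elastic solver."""

import numpy as np
import pytest

from tavrisk import fem
from tavrisk.materials import MaterialParams
from tavrisk.records import AorticRootGeometry
from tavrisk.valves import ValveDesign

MAT = MaterialParams(3.0, 0.45, 1800.0)


@pytest.fixture(scope="module")
def coarse_mesh(geometry):
    return fem.build_annulus_mesh(geometry, (16, 3, 2))


@pytest.fixture(scope="module")
def coarse_system(coarse_mesh):
    return fem.ElasticSystem(coarse_mesh, MAT)


class TestMesh:
    def test_default_resolution_element_count(self, geometry):
        mesh = fem.build_annulus_mesh(geometry)
        assert mesh.n_elements == 7820

    def test_minimal_resolution_counts(self, geometry):
        mesh = fem.build_annulus_mesh(geometry, (4, 1, 1))
        assert mesh.n_elements == 4
        assert mesh.n_nodes == 16

    def test_every_inner_surface_node_is_boundary(self, coarse_mesh):
        ids = coarse_mesh.boundary_node_ids
        assert np.allclose(coarse_mesh.node_r[ids], coarse_mesh.inner_radius)
        # boundary xor free covers all nodes
        assert np.intersect1d(ids, coarse_mesh.free_node_ids).size == 0
        assert ids.size + coarse_mesh.free_node_ids.size == coarse_mesh.n_nodes

    def test_tributary_area_sums_to_inner_surface(self, coarse_mesh):
        total = coarse_mesh.tributary_area.sum()
        exact = 2.0 * np.pi * coarse_mesh.inner_radius * coarse_mesh.height
        assert total == pytest.approx(exact, rel=0.01)

    def test_degenerate_geometry_rejected(self, geometry):
        import dataclasses

        with pytest.raises(ValueError):
            bad = dataclasses.replace(geometry, wall_thickness=-1.0)

    def test_too_coarse_resolution_rejected(self, geometry):
        with pytest.raises(ValueError):
            fem.build_annulus_mesh(geometry, (3, 1, 1))

    def test_node_ordering_phi_major(self, coarse_mesh):
        # first block of nodes shares phi index 0
        n_block = (coarse_mesh.resolution[1] + 1) * (coarse_mesh.resolution[2] + 1)
        assert np.allclose(coarse_mesh.node_phi_deg[:n_block], 0.0)


class TestBoundaryCondition:
    def test_matched_valve_no_calcium_gives_zero_displacement(self, coarse_mesh, geometry):
        valve = ValveDesign(size=2.0 * geometry.inner_radius, theta_deg=0.0)
        bc = fem.make_boundary_condition(coarse_mesh, geometry, valve)
        inner_vals = [v for k, v in bc.dirichlet.items()]
        assert np.allclose(inner_vals, 0.0)

    def test_vacancy_mask_matches_independent_predicate(self, geometry):
        mesh = fem.build_annulus_mesh(geometry, (92, 3, 1))
        valve = ValveDesign(size=27.0, theta_deg=90.0)
        bc = fem.make_boundary_condition(mesh, geometry, valve)
        # independent angular predicate over inner nodes
        inner = mesh.boundary_node_ids
        phi = mesh.node_phi_deg[inner]
        expected = inner[(phi < 45.0) | (phi > 315.0)]
        assert np.array_equal(np.sort(bc.vacant_node_ids), np.sort(expected))
        prescribed_nodes = {k // 3 for k in bc.dirichlet if k % 3 == 0}
        assert prescribed_nodes.isdisjoint(set(bc.vacant_node_ids.tolist()))

    def test_full_circle_vacancy_rejected(self):
        with pytest.raises(ValueError):
            ValveDesign(size=27.0, theta_deg=360.0)

    def test_unknown_axial_constraint_rejected(self, coarse_mesh, geometry):
        with pytest.raises(ValueError):
            fem.make_boundary_condition(
                coarse_mesh, geometry, ValveDesign(size=27.0), axial_constraint="sideways"
            )

    def test_calcium_profile_adds_local_displacement(self, coarse_mesh, geometry):
        profile = np.zeros(16)
        profile[0] = 3.0
        valve = ValveDesign(size=2.0 * geometry.inner_radius + 2.0, theta_deg=0.0)
        bc = fem.make_boundary_condition(coarse_mesh, geometry, valve, d_profile=profile)
        u = bc.u_radial
        phi = coarse_mesh.node_phi_deg[coarse_mesh.boundary_node_ids]
        in_sector = (phi >= 0.0) & (phi < 22.5)
        assert np.allclose(u[in_sector], 4.0)
        assert np.allclose(u[~in_sector], 1.0)


class TestSolver:
    def test_zero_prescription_zero_stress(self, coarse_system, geometry):
        valve = ValveDesign(size=2.0 * geometry.inner_radius, theta_deg=0.0)
        bc = fem.make_boundary_condition(coarse_system.mesh, geometry, valve)
        field = coarse_system.solve(bc)
        assert np.abs(field.von_mises).max() < 1e-12

    def test_linearity_doubling(self, coarse_system, geometry):
        valve = ValveDesign(size=2.0 * geometry.inner_radius + 2.0, theta_deg=30.0)
        bc = fem.make_boundary_condition(coarse_system.mesh, geometry, valve)
        f1 = coarse_system.solve(bc)
        f2 = coarse_system.solve(bc.scaled(2.0))
        assert np.allclose(f2.von_mises, 2.0 * f1.von_mises, rtol=1e-10, atol=1e-12)
        assert np.allclose(f2.stress_voigt, 2.0 * f1.stress_voigt, rtol=1e-10, atol=1e-12)

    def test_rigid_translation_is_stress_free(self, coarse_system):
        mesh = coarse_system.mesh
        # prescribe a rigid x-translation on every inner-surface dof triple
        u0 = 0.7
        dirichlet = {}
        for node in mesh.boundary_node_ids:
            dirichlet[3 * int(node)] = u0
            dirichlet[3 * int(node) + 1] = 0.0
            dirichlet[3 * int(node) + 2] = 0.0
        field = coarse_system.solve(
            fem.BoundaryCondition(dirichlet, 0.0, np.zeros(0), np.zeros(0, dtype=int))
        )
        scale = MAT.youngs_modulus * u0 / mesh.wall_thickness
        assert field.von_mises.max() < 1e-8 * scale
        assert np.allclose(field.displacement[:, 0], u0, atol=1e-9)

    def test_no_constraints_raises_rigid_mode_error(self, coarse_system):
        with pytest.raises(fem.RigidModeError):
            coarse_system.solve_displacement({})

    def test_determinism_bitwise(self, coarse_system, geometry):
        valve = ValveDesign(size=27.0, theta_deg=10.0)
        bc = fem.make_boundary_condition(coarse_system.mesh, geometry, valve)
        f1 = coarse_system.solve(bc)
        f2 = coarse_system.solve(bc)
        assert np.array_equal(f1.von_mises, f2.von_mises)

    def test_residual_is_small(self, coarse_system, geometry):
        bc = fem.make_boundary_condition(
            coarse_system.mesh, geometry, ValveDesign(size=28.0, theta_deg=0.0)
        )
        assert coarse_system.solve(bc).residual < 1e-8


class TestLame:
    def test_hoop_stress_matches_closed_form_and_refines(self, geometry):
        """Plane-strain thick-cylinder oracle at two resolutions."""
        errors = []
        for res in ((24, 2, 2), (48, 2, 4)):
            mesh = fem.build_annulus_mesh(geometry, res)
            system = fem.ElasticSystem(mesh, MAT)
            u0 = 1.0
            bc = fem.make_boundary_condition(
                mesh, geometry,
                ValveDesign(size=2.0 * (geometry.inner_radius + u0)),
                axial_constraint="full",
            )
            field = system.solve(bc)
            a = geometry.inner_radius
            b = a + geometry.wall_thickness
            lam, mu = MAT.lame_lambda, MAT.lame_mu
            A = u0 / (a + (lam + mu) * b**2 / (mu * a))
            B = (lam + mu) * A * b**2 / mu
            n_rad = res[2]
            dr = geometry.wall_thickness / n_rad
            inner = mesh.boundary_node_ids
            phi = np.deg2rad(mesh.node_phi_deg[inner])
            s = field.stress_voigt[inner]
            hoop_fem = (
                np.sin(phi) ** 2 * s[:, 0] + np.cos(phi) ** 2 * s[:, 1]
                - 2 * np.sin(phi) * np.cos(phi) * s[:, 3]
            )
            # recovery averages element-center values: compare at a + dr/2
            r_rec = a + dr / 2.0
            hoop_exact = 2 * (lam + mu) * A + 2 * mu * B / r_rec**2
            errors.append(abs(hoop_fem.mean() / hoop_exact - 1.0))
        assert errors[0] < 0.05
        assert errors[1] <= errors[0] + 1e-12  # refinement does not degrade


class TestConductionZone:
    def test_node_count_matches_predicate_oracle(self, geometry):
        mesh = fem.build_annulus_mesh(geometry, (92, 17, 5))
        ids = fem.conduction_zone_node_ids(mesh, band_height=4.0, half_angle_deg=45.0)
        brute = [
            n
            for n in range(mesh.n_nodes)
            if mesh.node_ir[n] == 0
            and mesh.node_z[n] <= 4.0 + 1e-9
            and min(mesh.node_phi_deg[n], 360.0 - mesh.node_phi_deg[n]) < 45.0
        ]
        assert ids.tolist() == brute

    def test_zero_field_gives_zero_vector_of_constant_length(self, coarse_system, geometry):
        mesh = coarse_system.mesh
        bc = fem.make_boundary_condition(
            mesh, geometry, ValveDesign(size=2.0 * geometry.inner_radius)
        )
        feats = fem.conduction_zone_features(coarse_system.solve(bc), mesh)
        assert np.allclose(feats, 0.0)
        assert feats.size == fem.conduction_zone_node_ids(mesh).size

    def test_empty_zone_rejected(self, coarse_mesh):
        with pytest.raises(ValueError):
            fem.conduction_zone_node_ids(coarse_mesh, band_height=-1.0)

    def test_mean_stress_monotone_in_vacancy_angle(self, coarse_system, geometry):
        mesh = coarse_system.mesh
        profile = np.zeros(16)
        profile[0] = profile[15] = 3.0  # calcium inside the conduction sector
        means = []
        for theta in (0.0, 30.0, 60.0, 90.0):
            bc = fem.make_boundary_condition(
                mesh, geometry, ValveDesign(size=27.0, theta_deg=theta), d_profile=profile
            )
            feats = fem.conduction_zone_features(coarse_system.solve(bc), mesh)
            means.append(feats.mean())
        assert all(means[i + 1] <= means[i] + 1e-12 for i in range(3))
        assert means[-1] < means[0]  # strict decrease with in-sector calcium
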