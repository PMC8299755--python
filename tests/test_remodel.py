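"""Virtual calcium displacement, rotation, and the angular thickness profile."""

import numpy as np
import pytest

from tavrisk.records import CalciumDeposit, cyl_to_cart, cart_to_cyl
from tavrisk.remodel import (
    GeometricInfeasibilityError,
    displace_deposit,
    local_thickness_profile,
    remodel_deposit,
    rotate_irregular_deposit,
)


def make_deposit(center=(8.0, 30.0, 5.0), thickness=2.0, **kwargs):
    defaults = dict(length=6.0, volume=120.0, cusp="NCC", shape="regular")
    defaults.update(kwargs)
    return CalciumDeposit(center=center, thickness=thickness, **defaults)


def rod(center, endpoints, thickness=2.0):
    return CalciumDeposit(
        center=center, thickness=thickness, length=6.0, volume=120.0,
        cusp="RCC", shape="irregular", endpoints=endpoints,
    )


class TestDisplace:
    def test_slab_contact_radius(self, geometry):
        # inner radius 12, center at 8, d = 2 -> displaced center at 11
        rd = displace_deposit(make_deposit(center=(8.0, 30.0, 5.0), thickness=2.0), geometry)
        assert rd.displaced_center == pytest.approx((11.0, 30.0, 5.0))
        assert rd.contacts_wall and rd.rotation_angle == 0.0

    def test_already_touching_is_identity(self, geometry):
        dep = make_deposit(center=(11.0, 30.0, 5.0), thickness=2.0)
        rd = displace_deposit(dep, geometry)
        assert rd.deposit == dep

    def test_volume_length_thickness_conserved(self, geometry):
        dep = make_deposit()
        rd = displace_deposit(dep, geometry)
        assert (rd.deposit.volume, rd.deposit.length, rd.deposit.thickness) == (
            dep.volume, dep.length, dep.thickness,
        )

    def test_brute_force_radial_line_search_agrees(self, geometry):
        # independent oracle: walk outward along the radial line until the
        # outer face (center radius + d/2) first touches the wall
        dep = make_deposit(center=(6.5, 123.0, 2.0), thickness=3.0)
        radii = np.arange(dep.center[0], geometry.inner_radius, 1e-5)
        touch = radii[radii + dep.thickness / 2.0 >= geometry.inner_radius]
        rd = displace_deposit(dep, geometry)
        assert rd.displaced_center[0] == pytest.approx(touch[0], abs=1e-4)

    def test_deposit_thicker_than_lumen_rejected(self, geometry):
        with pytest.raises(GeometricInfeasibilityError):
            displace_deposit(make_deposit(thickness=13.0, center=(5.0, 0.0, 5.0)), geometry)

    def test_center_outside_lumen_rejected(self, geometry):
        with pytest.raises(GeometricInfeasibilityError):
            displace_deposit(make_deposit(center=(12.5, 0.0, 5.0)), geometry)


class TestRotate:
    def test_endpoints_on_wall_is_identity(self, geometry):
        a = geometry.inner_radius
        center = cart_to_cyl(0.5 * (cyl_to_cart((a, 20.0, 3.0)) + cyl_to_cart((a, 50.0, 7.0))))
        dep = rod(center, ((a, 20.0, 3.0), (a, 50.0, 7.0)))
        rd = rotate_irregular_deposit(dep, geometry)
        assert rd.rotation_angle == 0.0
        assert rd.contacts_wall

    def test_matches_fine_grid_oracle(self, geometry):
        # endpoints at radii 10 and 11 inside the 12 mm wall, chord 6 mm
        a = geometry.inner_radius
        e1c = np.array([10.0, 0.0, 4.0])
        # place e2 at radius 11 and chord 6 from e1
        dz = 2.0
        d_xy = np.sqrt(6.0**2 - dz**2)
        # choose direction so |e2|_xy = 11
        for ang in np.linspace(0, 2 * np.pi, 7201):
            cand = e1c + d_xy * np.array([np.cos(ang), np.sin(ang), 0.0]) + [0, 0, dz]
            if abs(np.hypot(cand[0], cand[1]) - 11.0) < 2e-3:
                e2c = cand
                break
        dep = rod(
            cart_to_cyl(0.5 * (e1c + e2c)),
            (cart_to_cyl(e1c), cart_to_cyl(e2c)),
        )
        rd = rotate_irregular_deposit(dep, geometry)

        # brute-force oracle on a 0.001 degree grid over the same axis
        from tavrisk.remodel import _rotation_matrix

        c = cyl_to_cart(dep.center)
        radial = np.array([c[0], c[1], 0.0])
        radial /= np.linalg.norm(radial)
        long_axis = e2c - e1c
        axis = np.cross(long_axis, radial)
        axis /= np.linalg.norm(axis)

        def gap(angle):
            rot = _rotation_matrix(axis, angle)
            worst = 0.0
            for e in (e1c, e2c):
                p = c + rot @ (e - c)
                worst = max(worst, abs(np.hypot(p[0], p[1]) - a))
            return worst

        grid = np.arange(-180.0, 180.0, 0.001)
        vals = np.array([gap(g) for g in grid])
        best = grid[np.argmin(vals)]
        assert rd.rotation_angle == pytest.approx(best, abs=0.01)
        assert gap(rd.rotation_angle) <= vals.min() + 1e-9

    def test_mirror_image_rotates_opposite(self, geometry):
        e1, e2 = (10.0, 10.0, 3.0), (10.5, 40.0, 7.0)
        center = cart_to_cyl(0.5 * (cyl_to_cart(e1) + cyl_to_cart(e2)))
        rd = rotate_irregular_deposit(rod(center, (e1, e2)), geometry)
        # mirror through the phi = 25 plane and in z about the centroid
        def mirror(pt):
            return (pt[0], (50.0 - pt[1]) % 360.0, 10.0 - pt[2])
        rdm = rotate_irregular_deposit(
            rod(mirror(center), (mirror(e1), mirror(e2))), geometry
        )
        assert abs(rdm.rotation_angle) == pytest.approx(abs(rd.rotation_angle), abs=1e-3)

    def test_chord_longer_than_diameter_rejected(self, geometry):
        dep = rod((0.1, 0.0, 5.0), ((12.6, 170.0, 5.0), (12.6, 350.0, 5.0)))
        with pytest.raises(GeometricInfeasibilityError):
            rotate_irregular_deposit(dep, geometry)

    def test_regular_deposit_rejected(self, geometry):
        with pytest.raises(ValueError):
            rotate_irregular_deposit(make_deposit(), geometry)


class TestRemodel:
    def test_idempotent(self, geometry):
        dep = make_deposit(center=(7.0, 200.0, 6.0), thickness=2.5)
        once = remodel_deposit(dep, geometry)
        twice = remodel_deposit(once.deposit, geometry)
        assert twice.deposit.center == pytest.approx(once.deposit.center)
        assert twice.rotation_angle == pytest.approx(0.0, abs=1e-6)

    def test_irregular_combines_displacement_and_rotation(self, geometry):
        e1, e2 = (9.0, 350.0, 2.0), (9.5, 20.0, 8.0)
        center = cart_to_cyl(0.5 * (cyl_to_cart(e1) + cyl_to_cart(e2)))
        rd = remodel_deposit(rod(center, (e1, e2)), geometry)
        assert rd.displaced_center[0] == pytest.approx(
            geometry.inner_radius - rd.deposit.thickness / 2.0
        )
        assert rd.deposit.volume == 120.0


class TestThicknessProfile:
    def test_no_deposits_all_zero(self, geometry):
        assert local_thickness_profile([], geometry, 16).tolist() == [0.0] * 16

    def test_single_deposit_fills_its_sector_only(self, geometry):
        # short deposit centered in sector 1 of 8 (45 deg sectors)
        dep = make_deposit(center=(8.0, 67.5, 5.0), thickness=3.2, length=2.0)
        profile = local_thickness_profile([displace_deposit(dep, geometry)], geometry, 8)
        assert profile[1] == pytest.approx(3.2)
        assert np.count_nonzero(profile) == 1

    def test_overlapping_deposits_take_max(self, geometry):
        deps = [
            displace_deposit(make_deposit(center=(8.0, 67.5, 5.0), thickness=2.0, length=2.0), geometry),
            displace_deposit(make_deposit(center=(8.0, 70.0, 5.0), thickness=4.0, length=2.0), geometry),
        ]
        profile = local_thickness_profile(deps, geometry, 8)
        assert profile[1] == pytest.approx(4.0)

    def test_too_few_sectors_rejected(self, geometry):
        with pytest.raises(ValueError):
            local_thickness_profile([], geometry, 3)
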