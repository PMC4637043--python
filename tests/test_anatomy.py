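"""Geometric fits, neck-shaft angle recovery and critical sections."""

import numpy as np
import pytest

from femrisk.anatomy import (FemoralAxes, cross_section_area, estimate_axes,
                             find_critical_sections, fit_axis, fit_sphere,
                             neck_shaft_angle)
from femrisk.phantom import (PhantomSpec, generate_cylinder_fixture,
                             generate_phantom)


def _random_rigid_transform(seed):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.normal(scale=30.0, size=3)


class TestSphereFit:
    def test_exact_points_recovered_to_machine_precision(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=(20, 3))
        pts = d / np.linalg.norm(d, axis=1, keepdims=True) * 5.0 + [1, 2, 3]
        centre, radius = fit_sphere(pts)
        np.testing.assert_allclose(centre, [1, 2, 3], atol=1e-9)
        assert radius == pytest.approx(5.0, abs=1e-9)

    def test_noisy_points_centre_error_small(self):
        rng = np.random.default_rng(42)
        d = rng.normal(size=(500, 3))
        pts = d / np.linalg.norm(d, axis=1, keepdims=True) * 25.0
        pts = pts + np.array([3.0, -7.0, 11.0]) + rng.normal(0.0, 0.1,
                                                             size=pts.shape)
        centre, radius = fit_sphere(pts)
        assert np.linalg.norm(centre - [3.0, -7.0, 11.0]) < 0.05
        assert radius == pytest.approx(25.0, abs=0.05)

    def test_coplanar_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        with pytest.raises(ValueError):
            fit_sphere(pts)

    def test_equivariance_under_rigid_transform(self):
        rng = np.random.default_rng(5)
        d = rng.normal(size=(60, 3))
        pts = d / np.linalg.norm(d, axis=1, keepdims=True) * 8.0 + [2, 1, -4]
        q, t = _random_rigid_transform(9)
        c0, r0 = fit_sphere(pts)
        c1, r1 = fit_sphere(pts @ q.T + t)
        np.testing.assert_allclose(c1, q @ c0 + t, atol=1e-9)
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestAxisFit:
    @staticmethod
    def _cylinder_surface_points(n=400, seed=11):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, 2 * np.pi, n)
        z = rng.uniform(0, 80.0, n)
        return np.column_stack([5 * np.cos(theta), 5 * np.sin(theta), z])

    def test_cylinder_surface_axis_within_one_degree(self):
        direction, _ = fit_axis(self._cylinder_surface_points())
        cos = abs(direction @ [0, 0, 1.0])
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 1.0

    def test_collinear_points_give_exact_direction(self):
        u = np.ones(3) / np.sqrt(3.0)
        pts = np.outer(np.linspace(-3, 9, 13), u)
        direction, _ = fit_axis(pts)
        np.testing.assert_allclose(np.abs(direction), u, atol=1e-12)

    def test_orientation_follows_reference(self):
        pts = np.outer(np.linspace(0, 10, 11), [0, 0, 1.0])
        d_up, _ = fit_axis(pts, orient=[0, 0, 1.0])
        d_down, _ = fit_axis(pts, orient=[0, 0, -1.0])
        assert d_up[2] > 0 > d_down[2]

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            fit_axis(np.zeros((5, 3)))

    def test_equivariance_under_rigid_transform(self):
        pts = self._cylinder_surface_points(seed=13)
        q, t = _random_rigid_transform(21)
        d0, c0 = fit_axis(pts)
        d1, c1 = fit_axis(pts @ q.T + t)
        assert min(np.linalg.norm(d1 - q @ d0),
                   np.linalg.norm(d1 + q @ d0)) < 1e-9
        np.testing.assert_allclose(c1, q @ c0 + t, atol=1e-9)


class TestNeckShaftAngle:
    @staticmethod
    def _axes(angle_deg):
        # neck direction at the requested angle from the proximal (+z)
        # shaft axis, head placed on the neck axis away from the shaft
        a = np.radians(angle_deg)
        neck_dir = np.array([np.sin(a), 0.0, np.cos(a)])
        head = -40.0 * neck_dir
        return FemoralAxes(head_centre=head, head_radius=20.0,
                           neck_axis=neck_dir, neck_point=head,
                           shaft_axis=np.array([0, 0, 1.0]),
                           shaft_point=np.array([0, 0, -50.0]))

    def test_orthogonal_axes_flagged_as_boundary(self):
        with pytest.warns(UserWarning, match="anatomical range"):
            angle = neck_shaft_angle(self._axes(90.0))
        assert angle == pytest.approx(90.0, abs=1e-9)

    def test_antiparallel_orientation_gives_180(self):
        with pytest.warns(UserWarning):
            angle = neck_shaft_angle(self._axes(180.0))
        assert angle == pytest.approx(180.0, abs=1e-6)

    def test_oblique_axes_exact(self):
        angle = neck_shaft_angle(self._axes(130.0))
        assert angle == pytest.approx(130.0, abs=1e-9)

    @pytest.mark.parametrize("true_angle", [110.0, 125.0, 140.0])
    def test_phantom_recovery_within_two_degrees(self, true_angle):
        mesh = generate_phantom(PhantomSpec(neck_shaft_angle=true_angle,
                                            seed=1))
        axes = estimate_axes(mesh)
        assert axes.neck_shaft_angle == pytest.approx(true_angle, abs=2.0)


class TestCrossSections:
    def test_cylinder_midplane_area(self):
        cyl = generate_cylinder_fixture(10.0, 50.0, 2.0, 500.0)
        area = cross_section_area(
            cyl, (np.array([0, 0, 25.0]), np.array([0, 0, 1.0])))
        assert area == pytest.approx(np.pi * 100.0, rel=0.02)

    def test_plane_outside_mesh_is_empty_with_warning(self):
        cyl = generate_cylinder_fixture(10.0, 50.0, 2.0, 500.0)
        with pytest.warns(UserWarning, match="does not intersect"):
            area = cross_section_area(
                cyl, (np.array([0, 0, 60.0]), np.array([0, 0, 1.0])))
        assert area == 0.0

    def test_area_invariant_under_rigid_rotation(self):
        cyl = generate_cylinder_fixture(6.0, 30.0, 2.5, 500.0)
        origin, normal = np.array([0, 0, 17.0]), np.array([0, 0, 1.0])
        a0 = cross_section_area(cyl, (origin, normal))
        q, t = _random_rigid_transform(2)
        rotated = type(cyl)(cyl.nodes @ q.T + t, cyl.tets, cyl.element_hu,
                            cyl.landmarks, None, cyl.metadata)
        a1 = cross_section_area(rotated, (q @ origin + t, q @ normal))
        assert a1 == pytest.approx(a0, rel=1e-9)

    def test_subtrochanteric_plane_definition(self, default_phantom,
                                              default_axes,
                                              default_sections):
        sub = next(s for s in default_sections
                   if s.label == "subtrochanteric")
        lt = default_phantom.landmarks["lesser_trochanter"]
        shaft = default_axes.shaft_axis / np.linalg.norm(
            default_axes.shaft_axis)
        np.testing.assert_allclose(sub.origin, lt - 50.0 * shaft, atol=1e-9)

    def test_smallest_neck_minimises_over_stations(self, default_phantom,
                                                   default_axes,
                                                   default_sections):
        sfn = next(s for s in default_sections if s.label == "smallest_neck")
        u = -default_axes.neck_axis
        head = default_axes.head_centre
        t_best = (sfn.origin - head) @ u
        for t in np.arange(t_best - 5.0, t_best + 5.0, 1.0):
            area = cross_section_area(default_phantom, (head + t * u, u))
            if area > 0:
                assert sfn.area <= area + 1e-9

    def test_waist_is_found_as_smallest_neck(self):
        spec = PhantomSpec(seed=1, neck_waist_depth=4.0,
                           neck_waist_position=0.35)
        mesh = generate_phantom(spec)
        axes = estimate_axes(mesh)
        sections = find_critical_sections(mesh, axes)
        sfn = next(s for s in sections if s.label == "smallest_neck")
        t_found = np.linalg.norm(sfn.origin - axes.head_centre)
        t_waist = (1.0 - spec.neck_waist_position) * spec.neck_length
        # within the waist width plus one sampling step of the machined dip
        assert abs(t_found - t_waist) <= spec.neck_waist_width + 1.0

    def test_constant_section_tie_breaks_toward_head(self):
        cyl = generate_cylinder_fixture(10.0, 90.0, 4.0, 500.0)
        cyl.landmarks["lesser_trochanter"] = np.array([0.0, 0.0, 30.0])
        axes = FemoralAxes(
            head_centre=np.array([0.0, 0.0, 90.0]), head_radius=5.0,
            neck_axis=np.array([0.0, 0.0, 1.0]),
            neck_point=np.array([0.0, 0.0, 60.0]),
            shaft_axis=np.array([1.0, 0.0, 0.0]),
            shaft_point=np.array([0.0, 0.0, 0.0]))
        sections = find_critical_sections(cyl, axes,
                                          subtrochanteric_offset=0.0)
        sfn = next(s for s in sections if s.label == "smallest_neck")
        # area is constant along the axis; the first sampled station (the
        # one nearest the head) must win
        t_found = (axes.head_centre - sfn.origin)[2]
        assert t_found == pytest.approx(0.50 * 90.0, abs=1e-9)
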