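"""Quadrature rules, section triangulation and the fracture risk index."""

from types import SimpleNamespace

import numpy as np
import pytest
import sympy

from femrisk.anatomy import SectionPlane
from femrisk.materials import bin_materials
from femrisk.section_energy import (TetLocator, evaluate_section,
                                    fracture_risk_index, gauss_rule,
                                    section_field_maxima,
                                    section_strain_energy,
                                    section_yield_energy,
                                    triangulate_section)
from femrisk.phantom import generate_cylinder_fixture

MID_PLANE = SectionPlane(np.array([0.0, 0.0, 25.0]),
                         np.array([0.0, 0.0, 1.0]), "mid", 0.0)


def _symbolic_triangle_integral(coeffs, degs, verts):
    """Exact integral of sum c * x^i y^j over an arbitrary triangle."""
    x, y, l1, l2 = sympy.symbols("x y l1 l2")
    (x0, y0), (x1, y1), (x2, y2) = verts
    xs = x0 + l1 * (x1 - x0) + l2 * (x2 - x0)
    ys = y0 + l1 * (y1 - y0) + l2 * (y2 - y0)
    jac = sympy.Abs((x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0))
    poly = sum(c * x**i * y**j for c, (i, j) in zip(coeffs, degs))
    inner = sympy.integrate(poly.subs({x: xs, y: ys}) * jac,
                            (l2, 0, 1 - l1))
    return float(sympy.integrate(inner, (l1, 0, 1)))


def _quadrature_integral(rule, coeffs, degs, verts):
    verts = np.asarray(verts, float)
    pts = rule.barycentric_points @ verts
    u, v = verts[1] - verts[0], verts[2] - verts[0]
    jac = abs(u[0] * v[1] - u[1] * v[0])
    vals = sum(c * pts[:, 0]**i * pts[:, 1]**j
               for c, (i, j) in zip(coeffs, degs))
    return float((rule.weights * vals).sum() * jac)


class TestGaussRules:
    @pytest.mark.parametrize("n", [3, 7])
    def test_weights_positive_and_sum_half(self, n):
        rule = gauss_rule(n)
        assert np.all(rule.weights > 0)
        assert rule.weights.sum() == pytest.approx(0.5, rel=1e-14)
        np.testing.assert_allclose(rule.barycentric_points.sum(axis=1), 1.0,
                                   rtol=1e-14)

    def test_constant_integrand_gives_triangle_area(self):
        verts = [(0.0, 0.0), (3.0, 0.0), (0.0, 2.0)]  # area 3
        assert _quadrature_integral(gauss_rule(3), [1.0], [(0, 0)],
                                    verts) == pytest.approx(3.0, rel=1e-14)

    @pytest.mark.parametrize("n,degree", [(3, 2), (7, 5)])
    def test_exactness_against_symbolic_oracle(self, n, degree):
        rule = gauss_rule(n)
        rng = np.random.default_rng(17)
        verts = rng.uniform(-2, 3, size=(3, 2))
        degs = [(i, j) for i in range(degree + 1)
                for j in range(degree + 1 - i)]
        coeffs = rng.uniform(-1, 1, size=len(degs))
        exact = _symbolic_triangle_integral(coeffs, degs, verts)
        approx = _quadrature_integral(rule, coeffs, degs, verts)
        assert approx == pytest.approx(exact, rel=1e-12)

    def test_three_point_not_exact_beyond_degree_two(self):
        verts = np.array([(0.0, 0.0), (1.0, 0.0), (0.0, 1.0)])
        exact = _symbolic_triangle_integral([1.0], [(3, 0)], verts)
        approx = _quadrature_integral(gauss_rule(3), [1.0], [(3, 0)], verts)
        assert abs(approx - exact) > 1e-6

    def test_unsupported_point_count_rejected(self):
        with pytest.raises(ValueError):
            gauss_rule(4)


@pytest.fixture(scope="module")
def cylinder():
    return generate_cylinder_fixture(10.0, 50.0, 2.0, 500.0)


class TestTriangulation:
    @pytest.mark.parametrize("mode", ["conforming", "independent"])
    def test_total_area_matches_section(self, cylinder, mode):
        tri = triangulate_section(cylinder, MID_PLANE, max_edge=5.0,
                                  mode=mode)
        exact = np.pi * 100.0
        assert tri.areas.sum() == pytest.approx(exact, rel=0.02)
        # sum |J|/2 equals the exact polygonal slice area
        conf = triangulate_section(cylinder, MID_PLANE, mode="conforming")
        assert tri.areas.sum() == pytest.approx(conf.areas.sum(), rel=1e-6)

    def test_refinement_increases_triangle_count(self, cylinder):
        coarse = triangulate_section(cylinder, MID_PLANE, max_edge=5.0)
        fine = triangulate_section(cylinder, MID_PLANE, max_edge=2.5)
        assert fine.m > coarse.m

    def test_centroids_contained_in_recorded_tets(self, cylinder):
        tri = triangulate_section(cylinder, MID_PLANE, mode="conforming")
        locator = TetLocator(cylinder)
        centroids = tri.to_3d(tri.triangles.mean(axis=1))
        p = cylinder.nodes[cylinder.tets[tri.containing_element]]
        tmat = np.linalg.inv(np.transpose(p[:, 1:] - p[:, :1], (0, 2, 1)))
        loc = np.einsum("mij,mj->mi", tmat, centroids - p[:, 0])
        bary = np.column_stack([1.0 - loc.sum(axis=1), loc])
        assert bary.min() >= -1e-9
        del locator

    def test_missing_plane_rejected(self, cylinder):
        far = SectionPlane(np.array([0, 0, 99.0]), np.array([0, 0, 1.0]),
                           "far", 0.0)
        with pytest.raises(ValueError):
            triangulate_section(cylinder, far)


def _fake_solution(mesh, energy_density):
    """Minimal stand-in exposing the fields section integration reads."""
    return SimpleNamespace(mesh=mesh,
                           element_energy_density=np.asarray(energy_density),
                           element_von_mises_stress=np.zeros(mesh.num_elements),
                           element_von_mises_strain=np.zeros(mesh.num_elements))


class TestSectionEnergy:
    def test_uniform_density_integrates_to_density_times_area(self, cylinder):
        u0 = 0.37
        tri = triangulate_section(cylinder, MID_PLANE)
        sol = _fake_solution(cylinder, np.full(cylinder.num_elements, u0))
        u = section_strain_energy(sol, tri, gauss_rule(3))
        assert u == pytest.approx(u0 * tri.areas.sum(), rel=1e-12)

    def test_conforming_quadrature_equals_brute_force_sum(
            self, default_phantom, solved_cases, default_sections):
        sol = solved_cases["fall"]
        tri = triangulate_section(default_phantom, default_sections[0],
                                  mode="conforming")
        brute = float((tri.areas
                       * sol.element_energy_density[tri.containing_element]
                       ).sum())
        for n in (3, 7):
            u = section_strain_energy(sol, tri, gauss_rule(n))
            assert u == pytest.approx(brute, rel=1e-12)

    def test_three_vs_seven_point_on_phantom(self, default_phantom,
                                             default_materials, solved_cases,
                                             default_sections):
        """Scaled-down integration-rule study: eta from the 3- and 7-point
        rules agrees within 2 percent at the smallest-neck section."""
        sol = solved_cases["fall"]
        sfn = default_sections[0]
        etas = {}
        for n in (3, 7):
            res = evaluate_section(sol, default_materials, sfn,
                                   rule=gauss_rule(n))
            etas[n] = res.eta
        assert abs(etas[3] - etas[7]) / etas[7] <= 0.02

    def test_section_edge_convergence(self, default_materials, solved_cases,
                                      default_sections):
        sol = solved_cases["fall"]
        e5 = evaluate_section(sol, default_materials, default_sections[0],
                              max_edge=5.0).eta
        e25 = evaluate_section(sol, default_materials, default_sections[0],
                               max_edge=2.5).eta
        assert abs(e5 - e25) / e25 <= 0.01


class TestYieldEnergy:
    def test_homogeneous_section_closed_form(self, cylinder):
        table = bin_materials(cylinder.element_hu, 50)
        tri = triangulate_section(cylinder, MID_PLANE)
        u_y = section_yield_energy(table, tri, gauss_rule(3), mesh=cylinder)
        bin0 = table.bins[0]
        expected = tri.areas.sum() * bin0.sigma_Y**2 / (2.0 * bin0.E)
        assert u_y == pytest.approx(expected, rel=1e-12)

    def test_unit_density_bin_reference_value(self):
        # A = 100 mm^2 at (E, sigma_Y) of unit ash density
        u_y = 100.0 * 116.0**2 / (2.0 * 10500.0)
        assert u_y == pytest.approx(64.076, abs=1e-3)

    def test_independent_of_quadrature_rule(self, cylinder):
        table = bin_materials(cylinder.element_hu, 50)
        tri = triangulate_section(cylinder, MID_PLANE)
        u3 = section_yield_energy(table, tri, gauss_rule(3), mesh=cylinder)
        u7 = section_yield_energy(table, tri, gauss_rule(7), mesh=cylinder)
        assert u3 == pytest.approx(u7, rel=1e-12)


class TestFractureRiskIndex:
    def test_threshold_at_equal_energies(self):
        assert fracture_risk_index(64.0, 64.0) == 1.0

    def test_nonpositive_yield_energy_rejected(self):
        with pytest.raises(ValueError):
            fracture_risk_index(1.0, 0.0)

    def test_quadratic_scaling_with_load(self, bar_assets):
        from conftest import axial_bar_case
        from femrisk.fea import solve
        bar = bar_assets["mesh"]
        table = bar_assets["materials"]
        plane = SectionPlane(np.array([50.0, 5.0, 5.0]),
                             np.array([1.0, 0.0, 0.0]), "mid", 0.0)
        etas = []
        for alpha in (1.0, 2.0):
            sol = (bar_assets["solution"] if alpha == 1.0
                   else solve(bar, table, axial_bar_case(bar, alpha * 1000.0)))
            etas.append(evaluate_section(sol, table, plane).eta)
        assert etas[1] == pytest.approx(4.0 * etas[0], rel=1e-9)

    def test_uniform_uniaxial_stress_closed_form(self, bar_assets):
        """On the homogeneous bar, eta equals (sigma / sigma_Y)^2."""
        plane = SectionPlane(np.array([50.0, 5.0, 5.0]),
                             np.array([1.0, 0.0, 0.0]), "mid", 0.0)
        res = evaluate_section(bar_assets["solution"], bar_assets["materials"],
                               plane)
        sigma = bar_assets["F"] / bar_assets["A"]
        sigma_y = bar_assets["materials"].bins[0].sigma_Y
        assert res.eta == pytest.approx((sigma / sigma_y) ** 2, rel=1e-6)


class TestFieldMaxima:
    def test_bar_section_maximum_is_f_over_a(self, bar_assets):
        plane = SectionPlane(np.array([50.0, 5.0, 5.0]),
                             np.array([1.0, 0.0, 0.0]), "mid", 0.0)
        tri = triangulate_section(bar_assets["mesh"], plane)
        vm_s, vm_e = section_field_maxima(bar_assets["solution"], tri)
        assert vm_s == pytest.approx(10.0, rel=0.05)
        assert vm_e == pytest.approx(0.01, rel=0.05)

    def test_zero_load_gives_zero_maxima(self, cylinder):
        tri = triangulate_section(cylinder, MID_PLANE)
        sol = _fake_solution(cylinder, np.zeros(cylinder.num_elements))
        assert section_field_maxima(sol, tri) == (0.0, 0.0)

    def test_maxima_monotone_in_element_set(self, bar_assets):
        sol = bar_assets["solution"]
        vm = sol.element_von_mises_stress
        small = vm[:10].max()
        assert vm[:100].max() >= small
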