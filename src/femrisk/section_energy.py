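"""Cross-section strain energy and the fracture risk index eta = U / U_Y.

The load-induced strain energy over a critical cross-section,

    U   = sum_e  int  u_hat dA  ~  sum_e sum_i  W_i |J| u_hat_i ,

and the maximum allowable (yield) strain energy,

    U_Y = sum_e  int  sigma_Y^2 / (2 E) dA ,

are integrated by Gaussian quadrature over a 2D triangulation of the
section, where u_hat = 1/2 sigma : eps is the strain-energy density of the
containing tetrahedron and (E, sigma_Y) come from its material bin.  Both
integrals carry a volumetric energy density over an area and are therefore
energies per unit thickness (N*mm/mm); the fracture risk index

    eta = U / U_Y

is their dimensionless ratio, with eta > 1 flagging possible fracture.

Two triangulation modes are provided: ``conforming`` fan-triangulates the
per-tet intersection polygons (integration is then exact for the
piecewise-constant density field and independent of the quadrature rule),
while ``independent`` re-meshes the section outline by ear clipping, as
when the section boundary is exported and meshed separately; integration
points are then located in the tet mesh individually, so the 3-point and
7-point rules differ slightly at element boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .anatomy import SectionPlane, plane_basis, section_outline, slice_polygons
from .fea import FESolution
from .materials import MaterialTable
from .phantom import TetMesh

__all__ = [
    "QuadratureRule",
    "SectionTriangulation",
    "SectionEnergyResult",
    "gauss_rule",
    "triangulate_section",
    "section_strain_energy",
    "section_yield_energy",
    "fracture_risk_index",
    "section_field_maxima",
    "evaluate_section",
    "TetLocator",
    "DEFAULT_SECTION_EDGE_MM",
]

DEFAULT_SECTION_EDGE_MM = 5.0  # converged section-mesh edge length


def _cross2(tris: np.ndarray) -> np.ndarray:
    """|z-component of cross product| per (m, 3, 2) triangle = |J|."""
    u = tris[:, 1] - tris[:, 0]
    v = tris[:, 2] - tris[:, 0]
    return np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])


# ----------------------------------------------------------------------------
# quadrature on the reference triangle (area 1/2, barycentric points)
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class QuadratureRule:
    """Symmetric Gauss rule on the reference triangle; weights sum to 1/2."""

    n: int
    barycentric_points: np.ndarray  # (n, 3)
    weights: np.ndarray             # (n,)

    @property
    def degree(self) -> int:
        return {3: 2, 7: 5}[self.n]


def gauss_rule(n: int) -> QuadratureRule:
    """Standard symmetric triangle Gauss rules with 3 or 7 points.

    n=3: interior points (2/3, 1/6, 1/6), exact to polynomial degree 2.
    n=7: centroid plus two symmetric orbits, exact to degree 5.
    """
    if n == 3:
        pts = np.array([[2 / 3, 1 / 6, 1 / 6],
                        [1 / 6, 2 / 3, 1 / 6],
                        [1 / 6, 1 / 6, 2 / 3]])
        w = np.full(3, 1 / 6)
    elif n == 7:
        s15 = np.sqrt(15.0)
        a1 = (6.0 + s15) / 21.0
        a2 = (6.0 - s15) / 21.0
        w1 = (155.0 + s15) / 2400.0
        w2 = (155.0 - s15) / 2400.0
        rows = [np.full(3, 1 / 3)]
        weights = [9.0 / 80.0]
        for a, w_orb in ((a1, w1), (a2, w2)):
            b = 1.0 - 2.0 * a
            rows += [[a, a, b], [a, b, a], [b, a, a]]
            weights += [w_orb] * 3
        pts, w = np.array(rows), np.array(weights)
    else:
        raise ValueError(f"unsupported rule n={n}; available: 3, 7")
    return QuadratureRule(n=n, barycentric_points=pts, weights=w)


# ----------------------------------------------------------------------------
# point location in the tet mesh
# ----------------------------------------------------------------------------

class TetLocator:
    """Barycentric point-in-tet queries with a nearest-tet fallback.

    Candidate tets come from a k-d tree over tet centroids; a point is in
    a tet when all barycentric coordinates are >= -1e-9.  Points on shared
    faces or (marginally) outside every tet fall back to the tet with the
    least barycentric violation, ties broken to the lowest tet index.
    """

    def __init__(self, mesh: TetMesh):
        self.mesh = mesh
        p = mesh.nodes[mesh.tets]
        self.origin = p[:, 0]
        self.tmat = np.linalg.inv(
            np.transpose(p[:, 1:] - p[:, :1], (0, 2, 1)))
        self.tree = cKDTree(p.mean(axis=1))
        # bound on centroid-to-point distance for containing tets
        self.radius = np.linalg.norm(
            p - p.mean(axis=1, keepdims=True), axis=2).max()

    def _bary_violation(self, point: np.ndarray, cand: np.ndarray) -> np.ndarray:
        loc = np.einsum("mij,mj->mi", self.tmat[cand], point - self.origin[cand])
        bary = np.column_stack([1.0 - loc.sum(axis=1), loc])
        return -bary.min(axis=1)  # <= 0 means inside

    def locate(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        points = np.atleast_2d(points)
        out = np.empty(points.shape[0], dtype=int)
        k = min(24, self.mesh.num_elements)
        _, neigh = self.tree.query(points, k=k)
        neigh = np.atleast_2d(neigh)
        for i, point in enumerate(points):
            cand = np.sort(neigh[i])
            viol = self._bary_violation(point, cand)
            if viol.min() > tol:
                # widen once to every tet whose centroid could contain it
                cand = np.sort(np.array(
                    self.tree.query_ball_point(point, self.radius * 1.01),
                    dtype=int))
                if cand.size == 0:
                    raise ValueError(
                        f"integration point {point} lies outside the mesh")
                viol = self._bary_violation(point, cand)
            best = int(cand[np.argmin(viol)])  # argmin -> lowest index on ties
            if viol.min() > 1e-6 * self.radius:
                raise ValueError(
                    f"integration point {point} lies outside all tets "
                    f"(nearest violation {viol.min():g})")
            out[i] = best
        return out


# ----------------------------------------------------------------------------
# section triangulation
# ----------------------------------------------------------------------------

@dataclass
class SectionTriangulation:
    """2D triangle mesh of one cross-section, in the plane's frame."""

    triangles: np.ndarray          # (m, 3, 2) vertices, mm
    containing_element: np.ndarray  # tet index per triangle (centroid rule)
    plane: SectionPlane
    basis: tuple                   # (origin, e1, e2) mapping 2D -> 3D
    mode: str                      # "conforming" | "independent"

    @property
    def m(self) -> int:
        return self.triangles.shape[0]

    @property
    def jacobian_dets(self) -> np.ndarray:
        """|J| per triangle = twice the triangle area (mm^2)."""
        return _cross2(self.triangles)

    @property
    def areas(self) -> np.ndarray:
        return 0.5 * self.jacobian_dets

    def to_3d(self, pts2d: np.ndarray) -> np.ndarray:
        origin, e1, e2 = self.basis
        return origin + np.outer(pts2d[..., 0].ravel(), e1) \
            + np.outer(pts2d[..., 1].ravel(), e2)


def _ear_clip(loop: np.ndarray) -> list[np.ndarray]:
    """Triangulate a simple polygon by ear clipping (2D, CCW)."""
    # enforce counter-clockwise orientation
    x, y = loop[:, 0], loop[:, 1]
    if 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) < 0:
        loop = loop[::-1]
    idx = list(range(loop.shape[0]))
    tris = []
    guard = 0
    scale = np.ptp(loop, axis=0).max()
    eps = 1e-12 * scale * scale
    while len(idx) > 3 and guard < 10 * len(idx) ** 2:
        n = len(idx)
        clipped = False
        for k in range(n):
            i0, i1, i2 = idx[k - 1], idx[k], idx[(k + 1) % n]
            a, b, c = loop[i0], loop[i1], loop[i2]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross <= eps:
                continue  # reflex or degenerate corner
            # no other loop vertex strictly inside the candidate ear
            others = [j for j in idx if j not in (i0, i1, i2)]
            if others and _any_point_in_triangle(loop[others], a, b, c):
                continue
            tris.append(np.array([a, b, c]))
            idx.pop(k)
            clipped = True
            break
        guard += 1
        if not clipped:
            # numerically stuck (collinear runs): drop the flattest corner
            n = len(idx)
            crosses = []
            for k in range(n):
                a, b, c = loop[idx[k - 1]], loop[idx[k]], loop[idx[(k + 1) % n]]
                crosses.append(abs((b[0] - a[0]) * (c[1] - a[1])
                                   - (b[1] - a[1]) * (c[0] - a[0])))
            idx.pop(int(np.argmin(crosses)))
    if len(idx) == 3:
        tris.append(loop[idx])
    return tris


def _any_point_in_triangle(pts, a, b, c) -> bool:
    d1 = (pts[:, 0] - a[0]) * (b[1] - a[1]) - (pts[:, 1] - a[1]) * (b[0] - a[0])
    d2 = (pts[:, 0] - b[0]) * (c[1] - b[1]) - (pts[:, 1] - b[1]) * (c[0] - b[0])
    d3 = (pts[:, 0] - c[0]) * (a[1] - c[1]) - (pts[:, 1] - c[1]) * (a[0] - c[0])
    return bool(np.any((d1 < 0) & (d2 < 0) & (d3 < 0)))


def _refine_to_edge(tris: list[np.ndarray], max_edge: float) -> np.ndarray:
    """Uniform 4:1 subdivision until every triangle edge <= max_edge."""
    tris = [np.asarray(t, dtype=float) for t in tris]
    out = []
    stack = list(tris)
    while stack:
        t = stack.pop()
        e = max(np.linalg.norm(t[1] - t[0]), np.linalg.norm(t[2] - t[1]),
                np.linalg.norm(t[0] - t[2]))
        if e <= max_edge:
            out.append(t)
            continue
        m01, m12, m20 = (t[0] + t[1]) / 2, (t[1] + t[2]) / 2, (t[2] + t[0]) / 2
        stack += [np.array([t[0], m01, m20]), np.array([m01, t[1], m12]),
                  np.array([m20, m12, t[2]]), np.array([m01, m12, m20])]
    return np.array(out)


def triangulate_section(mesh: TetMesh, plane, max_edge: float = DEFAULT_SECTION_EDGE_MM,
                        mode: str = "independent") -> SectionTriangulation:
    """Triangulate the plane / mesh intersection with edges <= ``max_edge``.

    ``conforming`` splits each per-tet intersection polygon, so triangles
    never straddle tets; ``independent`` ear-clips the merged section
    outline, mirroring a separately generated 2D mesh of the exported
    boundary.  In both modes the summed triangle area equals the exact
    section area.  Containing elements are assigned by triangle centroid.
    """
    origin, normal = _plane_args(plane)
    n, e1, e2 = plane_basis(normal)
    proj = np.column_stack([e1, e2])

    polys = slice_polygons(mesh, origin, n)
    if not polys:
        raise ValueError("plane does not intersect the mesh")
    exact_area = 0.0
    for _, verts in polys:
        v2 = (verts - origin) @ proj
        exact_area += abs(0.5 * np.sum(
            v2[:, 0] * np.roll(v2[:, 1], -1) - np.roll(v2[:, 0], -1) * v2[:, 1]))

    triangles = tags = None
    if mode == "independent":
        # re-mesh the merged outline; valid only for simply connected
        # sections -- a faceted surface can carry small handles near the
        # trochanteric junction, detected here as an area mismatch
        loops, _ = section_outline(mesh, origin, n)
        pieces = []
        for loop in loops:
            pieces += _ear_clip(loop)
        if pieces:
            cand = _refine_to_edge(pieces, max_edge)
            areas = 0.5 * _cross2(cand)
            if abs(areas.sum() - exact_area) <= 1e-9 * exact_area:
                try:
                    locator = TetLocator(mesh)
                    centroids3d = origin + cand.mean(axis=1) @ proj.T
                    tags = locator.locate(centroids3d)
                    triangles = cand
                except ValueError:
                    triangles = tags = None
    elif mode != "conforming":
        raise ValueError(f"unknown triangulation mode {mode!r}")

    if triangles is None:
        # exact per-tet polygon decomposition (always available)
        tris, tag_list = [], []
        for tet_idx, verts in polys:
            v2 = (verts - origin) @ proj
            pieces = [np.array([v2[0], v2[k], v2[k + 1]])
                      for k in range(1, v2.shape[0] - 1)]
            refined = _refine_to_edge(pieces, max_edge)
            tris.append(refined)
            tag_list += [tet_idx] * refined.shape[0]
        triangles = np.concatenate(tris)
        tags = np.array(tag_list, dtype=int)
        if mode == "independent":
            mode = "conforming"  # record what was actually built

    # drop degenerate slivers produced by grazing cuts
    areas = 0.5 * _cross2(triangles)
    total = areas.sum()
    keep = areas > 1e-14 * max(total, 1.0)
    triangles, tags = triangles[keep], tags[keep]

    if isinstance(plane, SectionPlane):
        section_plane = plane
    else:
        section_plane = SectionPlane(np.asarray(origin, float), n, "section", total)
    return SectionTriangulation(triangles=triangles, containing_element=tags,
                                plane=section_plane, basis=(origin, e1, e2),
                                mode=mode)


def _plane_args(plane):
    if isinstance(plane, SectionPlane):
        return np.asarray(plane.origin, float), np.asarray(plane.normal, float)
    origin, normal = plane
    return np.asarray(origin, float), np.asarray(normal, float)


# ----------------------------------------------------------------------------
# quadrature accumulation
# ----------------------------------------------------------------------------

def _integrate_density(tri: SectionTriangulation, rule: QuadratureRule,
                       element_density: np.ndarray,
                       locator: TetLocator | None) -> float:
    """sum_e sum_i W_i |J| f(tet at point i) for per-tet-constant f."""
    pts_b = rule.barycentric_points       # (n, 3)
    w = rule.weights                      # (n,)
    jac = tri.jacobian_dets               # (m,)
    pts2d = np.einsum("nk,mkd->mnd", pts_b, tri.triangles)  # (m, n, 2)
    if locator is None:
        dens = element_density[tri.containing_element][:, None]  # (m, 1)
    else:
        pts3d = tri.to_3d(pts2d).reshape(tri.m, rule.n, 3)
        tets = locator.locate(pts3d.reshape(-1, 3)).reshape(tri.m, rule.n)
        dens = element_density[tets]      # (m, n)
    return float(np.einsum("n,m,mn->", w, jac, np.broadcast_to(dens, (tri.m, rule.n))))


def section_strain_energy(solution: FESolution, tri: SectionTriangulation,
                          rule: QuadratureRule | None = None) -> float:
    """Load-induced section strain energy U (N*mm per mm thickness).

    The strain-energy density at each integration point is that of the
    containing tet (constant per linear tet).  In conforming mode the
    containing tet is the triangle's tag; in independent mode each
    integration point is located in the mesh individually.
    """
    rule = rule or gauss_rule(3)
    locator = TetLocator(solution.mesh) if tri.mode == "independent" else None
    return _integrate_density(tri, rule, solution.element_energy_density, locator)


def section_yield_energy(materials: MaterialTable, tri: SectionTriangulation,
                         rule: QuadratureRule | None = None,
                         mesh: TetMesh | None = None) -> float:
    """Maximum allowable section strain energy U_Y (N*mm per mm thickness).

    Integrates the yield strain-energy density sigma_Y^2 / (2 E) of the
    containing element's material bin; independent of the load case.
    """
    rule = rule or gauss_rule(3)
    locator = TetLocator(mesh) if (tri.mode == "independent" and mesh is not None) else None
    return _integrate_density(tri, rule, materials.element_yield_energy_density,
                              locator)


def fracture_risk_index(u: float, u_y: float) -> float:
    """eta = U / U_Y; dimensionless, eta > 1 flags possible fracture."""
    if u_y <= 0:
        raise ValueError("yield strain energy must be positive")
    return u / u_y


def section_field_maxima(solution: FESolution,
                         tri: SectionTriangulation) -> tuple[float, float]:
    """(max von Mises stress MPa, max von Mises strain) over section tets."""
    tets = np.unique(tri.containing_element)
    if tets.size == 0:
        raise ValueError("section intersects no elements")
    return (float(solution.element_von_mises_stress[tets].max()),
            float(solution.element_von_mises_strain[tets].max()))


@dataclass
class SectionEnergyResult:
    """U, U_Y and eta for one critical cross-section and load case."""

    label: str
    area: float                 # mm^2
    U: float                    # N*mm per mm thickness
    U_Y: float                  # N*mm per mm thickness
    eta: float
    rule_n: int
    max_von_mises_stress: float  # MPa
    max_von_mises_strain: float
    configuration: str = ""
    triangulation: SectionTriangulation = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "configuration": self.configuration,
            "area_mm2": self.area,
            "U": self.U,
            "U_Y": self.U_Y,
            "eta": self.eta,
            "rule_n": self.rule_n,
            "max_von_mises_stress_MPa": self.max_von_mises_stress,
            "max_von_mises_strain": self.max_von_mises_strain,
        }


def evaluate_section(solution: FESolution, materials: MaterialTable,
                     plane: SectionPlane,
                     max_edge: float = DEFAULT_SECTION_EDGE_MM,
                     rule: QuadratureRule | None = None,
                     mode: str = "independent") -> SectionEnergyResult:
    """Full section evaluation: triangulate, integrate U and U_Y, form eta."""
    rule = rule or gauss_rule(3)
    tri = triangulate_section(solution.mesh, plane, max_edge=max_edge, mode=mode)
    u = section_strain_energy(solution, tri, rule)
    u_y = section_yield_energy(materials, tri, rule, mesh=solution.mesh)
    vm_s, vm_e = section_field_maxima(solution, tri)
    return SectionEnergyResult(
        label=plane.label, area=float(tri.areas.sum()), U=u, U_Y=u_y,
        eta=fracture_risk_index(u, u_y), rule_n=rule.n,
        max_von_mises_stress=vm_s, max_von_mises_strain=vm_e,
        configuration=getattr(solution.load, "configuration", ""),
        triangulation=tri,
    )
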