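"""Femoral anatomy from mesh geometry: axes, neck-shaft angle, sections.

The joint centre is found by least-squares sphere fitting on the femoral
head surface; shaft and neck axes by line fits on geometric capture
regions (the shaft by a principal-direction fit of its surface band, the
neck by a chain of cross-section centroids anchored at the head centre,
which is robust for the short wide neck).  The three clinically critical
planes are located from the axes:

* smallest femoral neck section  -- minimum-area plane normal to the neck
  axis over a sampled neck segment;
* intertrochanteric section      -- maximum-area plane normal to the neck
  axis over the trochanteric segment;
* subtrochanteric section        -- plane normal to the shaft axis 50 mm
  distal to the lesser trochanter.

Cross-section areas are exact polygon areas of the plane / tet-mesh
intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .phantom import TetMesh

__all__ = [
    "FemoralAxes",
    "SectionPlane",
    "fit_sphere",
    "fit_axis",
    "neck_shaft_angle",
    "estimate_axes",
    "find_critical_sections",
    "cross_section_area",
    "slice_polygons",
    "section_outline",
    "plane_basis",
    "SUBTROCHANTERIC_OFFSET_MM",
]

SUBTROCHANTERIC_OFFSET_MM = 50.0  # five centimetres below the lesser trochanter
STATION_STEP_MM = 1.0             # plane-sweep step, matching 1 mm slice spacing


@dataclass
class FemoralAxes:
    """Fitted femoral head sphere, neck axis and shaft axis."""

    head_centre: np.ndarray
    head_radius: float
    neck_axis: np.ndarray   # unit vector, oriented from shaft toward the head
    neck_point: np.ndarray
    shaft_axis: np.ndarray  # unit vector, oriented proximally
    shaft_point: np.ndarray
    neck_shaft_angle: float | None = None  # degrees


@dataclass
class SectionPlane:
    """One critical cross-section plane with its measured area."""

    origin: np.ndarray
    normal: np.ndarray
    label: str   # smallest_neck | intertrochanteric | subtrochanteric
    area: float  # mm^2


# ----------------------------------------------------------------------------
# geometric fits
# ----------------------------------------------------------------------------

def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares sphere fit.

    Minimises sum (|p - c|^2 - r^2)^2, which is linear in (c, r^2 - |c|^2).
    Requires at least 4 non-coplanar points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 4 or pts.shape[1] != 3:
        raise ValueError("sphere fit needs >= 4 points of dimension 3")
    a = np.column_stack([2.0 * pts, np.ones(pts.shape[0])])
    b = (pts**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 4:
        raise ValueError("degenerate (coplanar) points: sphere fit is singular")
    centre = sol[:3]
    r2 = sol[3] + centre @ centre
    if r2 <= 0:
        raise ValueError("sphere fit produced nonpositive radius")
    return centre, float(np.sqrt(r2))


def fit_axis(points: np.ndarray,
             orient: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Principal direction of a point cloud through its centroid.

    Surrogate for a best-fit ruled-surface direction on near-cylindrical
    surfaces.  The sign is normalised toward ``orient`` when given,
    otherwise so the largest-magnitude component is positive.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("axis fit needs >= 3 points")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    if not np.any(np.linalg.norm(centred, axis=1) > 0):
        raise ValueError("zero-spread point cloud: axis undefined")
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    direction = vt[0]
    if orient is not None:
        if direction @ np.asarray(orient, float) < 0:
            direction = -direction
    elif direction[np.argmax(np.abs(direction))] < 0:
        direction = -direction
    return direction, centroid


def neck_shaft_angle(axes: FemoralAxes) -> float:
    """Angle (degrees) between neck and shaft axes under the 3D convention.

    The neck axis is oriented away from the head centre and the shaft axis
    proximally; anatomical values lie in (90, 180), boundary cases are
    flagged with a warning.
    """
    neck = np.asarray(axes.neck_axis, float)
    neck = neck / np.linalg.norm(neck)
    # orient away from the head: from the head centre toward the shaft
    toward_shaft = np.asarray(axes.shaft_point, float) - np.asarray(
        axes.head_centre, float)
    if neck @ toward_shaft < 0:
        neck = -neck
    shaft = np.asarray(axes.shaft_axis, float)
    shaft = shaft / np.linalg.norm(shaft)
    # orient proximally: toward the head end of the shaft
    if shaft @ (np.asarray(axes.head_centre, float)
                - np.asarray(axes.shaft_point, float)) < 0:
        shaft = -shaft
    angle = float(np.degrees(np.arccos(np.clip(neck @ shaft, -1.0, 1.0))))
    if not 90.0 < angle < 180.0:
        warnings.warn(
            f"neck-shaft angle {angle:.1f} deg outside anatomical range (90, 180)"
        )
    return angle


# ----------------------------------------------------------------------------
# plane / mesh intersection
# ----------------------------------------------------------------------------

def plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit normal and a right-handed in-plane orthonormal basis (e1, e2)."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    helper = np.zeros(3)
    helper[np.argmin(np.abs(n))] = 1.0
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return n, e1, e2


def _signed_distances(mesh: TetMesh, origin, normal) -> np.ndarray:
    d = (mesh.nodes - np.asarray(origin, float)) @ np.asarray(normal, float)
    # nudge nodes exactly on the plane to one side for a consistent topology
    scale = max(np.abs(d).max(), 1.0)
    eps = 1e-12 * scale
    d[np.abs(d) < eps] = eps
    return d


def _edge_cut(p_i, p_j, d_i, d_j):
    t = d_i / (d_i - d_j)
    return p_i + t * (p_j - p_i)


def slice_polygons(mesh: TetMesh, origin, normal):
    """Intersection polygons of the plane with every cut tet.

    Returns a list of (tet_index, vertices) where vertices is a (3, 3) or
    (4, 3) array ordered around the convex polygon.
    """
    d = _signed_distances(mesh, origin, normal)
    signs = d[mesh.tets] > 0
    npos = signs.sum(axis=1)
    cut = np.where((npos > 0) & (npos < 4))[0]
    polys = []
    for e in cut:
        tet = mesh.tets[e]
        pos = tet[signs[e]]
        neg = tet[~signs[e]]
        if len(neg) in (1, 3):
            apex_side = neg if len(neg) == 1 else pos
            base_side = pos if len(neg) == 1 else neg
            a = apex_side[0]
            verts = [_edge_cut(mesh.nodes[a], mesh.nodes[b], d[a], d[b])
                     for b in base_side]
        else:  # 2-2 split: quad ordered by shared-vertex adjacency
            (a, b), (c, e2) = neg, pos
            verts = [
                _edge_cut(mesh.nodes[a], mesh.nodes[c], d[a], d[c]),
                _edge_cut(mesh.nodes[a], mesh.nodes[e2], d[a], d[e2]),
                _edge_cut(mesh.nodes[b], mesh.nodes[e2], d[b], d[e2]),
                _edge_cut(mesh.nodes[b], mesh.nodes[c], d[b], d[c]),
            ]
        polys.append((int(e), np.array(verts)))
    return polys


def _polygon_area_centroid(verts2d: np.ndarray) -> tuple[float, np.ndarray]:
    x, y = verts2d[:, 0], verts2d[:, 1]
    xr, yr = np.roll(x, -1), np.roll(y, -1)
    cross = x * yr - xr * y
    area = 0.5 * cross.sum()
    if abs(area) < 1e-300:
        return 0.0, verts2d.mean(axis=0)
    cx = ((x + xr) * cross).sum() / (6.0 * area)
    cy = ((y + yr) * cross).sum() / (6.0 * area)
    return abs(area), np.array([cx, cy])


def _slice_measure(mesh: TetMesh, origin, normal):
    """(total area, area centroid in 3D) of one plane slice."""
    n, e1, e2 = plane_basis(normal)
    origin = np.asarray(origin, float)
    total, moment = 0.0, np.zeros(2)
    for _, verts in slice_polygons(mesh, origin, n):
        v2 = (verts - origin) @ np.column_stack([e1, e2])
        a, c = _polygon_area_centroid(v2)
        total += a
        moment += a * c
    if total == 0.0:
        return 0.0, None
    c2 = moment / total
    return total, origin + c2[0] * e1 + c2[1] * e2


def cross_section_area(mesh: TetMesh, plane) -> float:
    """Area (mm^2) of the plane / mesh intersection polygon(s).

    ``plane`` may be a :class:`SectionPlane` or an (origin, normal) pair.
    Returns 0 with a warning when the plane misses the mesh.
    """
    origin, normal = _plane_args(plane)
    area, _ = _slice_measure(mesh, origin, normal)
    if area == 0.0:
        warnings.warn("plane does not intersect the mesh; area is zero")
    return area


def _plane_args(plane):
    if isinstance(plane, SectionPlane):
        return plane.origin, plane.normal
    origin, normal = plane
    return np.asarray(origin, float), np.asarray(normal, float)


def section_outline(mesh: TetMesh, origin, normal):
    """Closed boundary loops of the plane slice, in plane coordinates.

    Each boundary triangle of the mesh cut by the plane contributes one
    segment whose endpoints are keyed by the mesh edge carrying them, so
    loops chain exactly without floating-point vertex matching.  Returns
    (loops, basis) where loops is a list of (k, 2) arrays and basis is
    (origin, e1, e2).
    """
    n, e1, e2 = plane_basis(normal)
    origin = np.asarray(origin, float)
    d = _signed_distances(mesh, origin, n)
    segments = []  # pairs of (edge_key, point2d)
    for tri in mesh.boundary_faces():
        s = d[tri] > 0
        if s.all() or (~s).all():
            continue
        pts = []
        for i in range(3):
            a, b = tri[i], tri[(i + 1) % 3]
            if (d[a] > 0) != (d[b] > 0):
                key = (int(min(a, b)), int(max(a, b)))
                p = _edge_cut(mesh.nodes[a], mesh.nodes[b], d[a], d[b])
                p2 = np.array([(p - origin) @ e1, (p - origin) @ e2])
                pts.append((key, p2))
        if len(pts) == 2:
            segments.append(pts)
    if not segments:
        return [], (origin, e1, e2)
    # chain segments into loops by edge key
    adjacency: dict[tuple, list] = {}
    for seg_idx, seg in enumerate(segments):
        for key, _ in seg:
            adjacency.setdefault(key, []).append(seg_idx)
    unused = set(range(len(segments)))
    loops = []
    while unused:
        start = min(unused)
        unused.discard(start)
        (k0, p0), (k1, p1) = segments[start]
        loop_pts = [p0, p1]
        current_key = k1
        while True:
            nxt = [s for s in adjacency.get(current_key, []) if s in unused]
            if not nxt:
                break
            s = nxt[0]
            unused.discard(s)
            (ka, pa), (kb, pb) = segments[s]
            if ka == current_key:
                loop_pts.append(pb)
                current_key = kb
            else:
                loop_pts.append(pa)
                current_key = ka
        if current_key == k0:
            loop_pts.pop()  # closing vertex repeats the first
        if len(loop_pts) >= 3:
            loops.append(np.array(loop_pts))
    return loops, (origin, e1, e2)


# ----------------------------------------------------------------------------
# axis estimation pipeline
# ----------------------------------------------------------------------------

def _fit_head(mesh: TetMesh, surf_pts: np.ndarray, seed_centre: np.ndarray,
              radius_guess: float) -> tuple[np.ndarray, float]:
    centre, radius = np.asarray(seed_centre, float), float(radius_guess)
    for _ in range(4):
        dist = np.linalg.norm(surf_pts - centre, axis=1)
        sel = np.abs(dist - radius) < 0.25 * radius
        if sel.sum() < 10:
            sel = dist < 1.2 * radius
        centre, radius = fit_sphere(surf_pts[sel])
    return centre, radius


def estimate_axes(mesh: TetMesh, head_radius_guess: float | None = None,
                  station_step: float = STATION_STEP_MM) -> FemoralAxes:
    """Estimate head sphere, shaft and neck axes and the neck-shaft angle.

    Landmarks seed the geometric capture regions; the estimate itself uses
    only the mesh surface.  The neck axis is obtained from a chain of
    cross-section centroids between the head surface and the trochanteric
    junction (detected by an area jump), then refined by a cylinder-axis
    fit on the neck surface band.
    """
    lm = mesh.landmarks
    if "head_centre" not in lm or "distal_end_centre" not in lm:
        raise ValueError("landmarks head_centre and distal_end_centre required")
    surf_idx = mesh.surface_nodes()
    surf_pts = mesh.nodes[surf_idx]

    r_guess = head_radius_guess or float(mesh.metadata.get("head_radius", 25.0))
    head_c, head_r = _fit_head(mesh, surf_pts, lm["head_centre"], r_guess)

    distal = np.asarray(lm["distal_end_centre"], float)
    seed_top = np.asarray(
        lm.get("greater_trochanter", lm.get("lesser_trochanter", head_c)), float)
    a0 = seed_top - distal
    a0 /= np.linalg.norm(a0)
    t = (surf_pts - distal) @ a0
    band = (t > 0.05 * t.max()) & (t < 0.55 * t.max())
    shaft_dir, shaft_pt = fit_axis(surf_pts[band], orient=a0)
    # refine with slice centroids: the centroid of any plane cut of a
    # circular shaft lies on its axis, so a line through the centroids is
    # insensitive to how the capture band was cut
    for _ in range(2):
        t_surf = (surf_pts - distal) @ shaft_dir
        stations = np.arange(0.08 * t_surf.max(), 0.55 * t_surf.max(), 4.0)
        cents = []
        for t_val in stations:
            area, centroid = _slice_measure(
                mesh, distal + t_val * shaft_dir, shaft_dir)
            if area > 0:
                cents.append(centroid)
        if len(cents) < 3:
            break
        shaft_dir, shaft_pt = fit_axis(np.array(cents), orient=shaft_dir)

    # --- neck axis: centroid chain, iterated, then cylinder refinement ---
    gt = np.asarray(lm.get("greater_trochanter", shaft_pt), float)
    u = gt - head_c
    u /= np.linalg.norm(u)  # rough head -> trochanter direction
    t_start = 1.08 * head_r
    point = head_c
    for _ in range(4):
        # cap the sweep before the trochanteric junction: stop short of the
        # closest approach to the shaft axis and on any clear area jump
        probe = FemoralAxes(head_c, head_r, -u, head_c, shaft_dir, shaft_pt)
        t_cap = 0.8 * _closest_approach_t(probe)
        centroids, areas = [], []
        baseline = None
        t_val = t_start
        while t_val < max(t_cap, t_start + 4 * station_step):
            area, centroid = _slice_measure(mesh, head_c + t_val * u, u)
            if area > 0:
                if baseline is None and len(areas) >= 4:
                    baseline = float(np.median(areas))
                if baseline is not None and area > 1.12 * baseline:
                    break
                centroids.append(centroid)
                areas.append(area)
            t_val += station_step
        if len(centroids) < 4:
            raise ValueError("could not sample enough neck stations")
        # the head centre and every clean slice centroid lie on the neck
        # axis, so the head centre anchors the direction with a long lever
        point = np.asarray(centroids).mean(axis=0)
        u = (point - head_c) / np.linalg.norm(point - head_c)
    neck_axis = -u  # convention: oriented from the shaft toward the head
    axes = FemoralAxes(head_centre=head_c, head_radius=head_r,
                       neck_axis=neck_axis, neck_point=np.asarray(point, float),
                       shaft_axis=shaft_dir, shaft_point=shaft_pt)
    axes.neck_shaft_angle = neck_shaft_angle(axes)
    return axes


# ----------------------------------------------------------------------------
# critical sections
# ----------------------------------------------------------------------------

def _closest_approach_t(axes: FemoralAxes) -> float:
    """Arc length along the neck axis from the head centre to the shaft axis."""
    u = -np.asarray(axes.neck_axis, float)  # away from the head
    u /= np.linalg.norm(u)
    s = np.asarray(axes.shaft_axis, float)
    s /= np.linalg.norm(s)
    w0 = np.asarray(axes.head_centre, float) - np.asarray(axes.shaft_point, float)
    a, b_, c = u @ u, u @ s, s @ s
    denom = a * c - b_ * b_
    if abs(denom) < 1e-12:
        return float(np.linalg.norm(w0))
    t = (b_ * (w0 @ s) - c * (w0 @ u)) / denom
    return float(abs(t))


def find_critical_sections(mesh: TetMesh, axes: FemoralAxes,
                           neck_fractions: tuple = (0.50, 0.80),
                           trochanteric_fractions: tuple = (0.80, 1.15),
                           step: float = STATION_STEP_MM,
                           subtrochanteric_offset: float = SUBTROCHANTERIC_OFFSET_MM,
                           ) -> list[SectionPlane]:
    """Locate the three critical planes from the fitted axes.

    Neck and trochanteric sweeps run along the neck axis away from the
    head centre over the given fractions of the head-centre-to-shaft-axis
    arc length; ties are broken toward the head.  The subtrochanteric
    plane sits ``subtrochanteric_offset`` mm distal to the lesser
    trochanter along the shaft axis.
    """
    if "lesser_trochanter" not in mesh.landmarks:
        raise ValueError("lesser_trochanter landmark required")
    u = -np.asarray(axes.neck_axis, float)
    u /= np.linalg.norm(u)
    head_c = np.asarray(axes.head_centre, float)
    l0 = _closest_approach_t(axes)

    def sweep(fractions, pick):
        best_t, best_area = None, None
        for t in np.arange(fractions[0] * l0, fractions[1] * l0 + 1e-9, step):
            area, _ = _slice_measure(mesh, head_c + t * u, u)
            if area == 0.0:
                continue
            # ties (to relative 1e-9) break toward the station nearest the
            # head, i.e. the first sampled one
            if best_area is None or pick(area, best_area):
                best_t, best_area = t, area
        if best_t is None:
            raise ValueError("all sampled stations produced empty sections")
        return best_t, best_area

    t_min, a_min = sweep(neck_fractions, lambda a, b: a < b * (1 - 1e-9))
    t_max, a_max = sweep(trochanteric_fractions, lambda a, b: a > b * (1 + 1e-9))

    shaft = np.asarray(axes.shaft_axis, float)
    shaft /= np.linalg.norm(shaft)
    if shaft @ (head_c - np.asarray(axes.shaft_point, float)) < 0:
        shaft = -shaft  # proximal
    lt = np.asarray(mesh.landmarks["lesser_trochanter"], float)
    sub_origin = lt - subtrochanteric_offset * shaft
    sub_area, _ = _slice_measure(mesh, sub_origin, shaft)
    if sub_area == 0.0:
        raise ValueError("subtrochanteric plane does not intersect the mesh")

    return [
        SectionPlane(head_c + t_min * u, u.copy(), "smallest_neck", a_min),
        SectionPlane(head_c + t_max * u, u.copy(), "intertrochanteric", a_max),
        SectionPlane(sub_origin, shaft.copy(), "subtrochanteric", sub_area),
    ]
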