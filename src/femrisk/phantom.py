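"""Synthetic proximal-femur phantoms and analytic solver fixtures.

Clinical QCT scans cannot ship with the package, so every downstream stage
(material mapping, FE solve, anatomy detection, section energy) is exercised
on synthetic geometry with known ground truth:

* a proximal-femur phantom -- cylindrical shaft, angled cylindrical neck and
  spherical head, a high-HU cortical shell over a low-HU cancellous interior,
  with stored landmarks and the constructed neck-shaft angle;
* a rectangular bar and a circular cylinder with uniform HU, whose
  displacement / area / volume have closed forms, for solver validation.

The phantom mesher tetrahedralises a body-centred-cubic point lattice
(Delaunay of a BCC lattice is the disphenoid honeycomb: congruent,
well-shaped tets with maximum edge equal to the lattice spacing) and keeps
the tets whose centroid lies inside the implicit shaft-neck-head solid.
Fixtures use fully structured meshes so their volumes are exact.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay

__all__ = [
    "PhantomSpec",
    "TetMesh",
    "generate_phantom",
    "generate_bar_fixture",
    "generate_cylinder_fixture",
    "save_vtk",
    "load_vtk",
    "save_csv",
    "load_csv",
]


# ----------------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of the synthetic proximal femur.

    Lengths in mm, intensities in HU.  Defaults describe an adult femur:
    head radius ~23 mm, neck radius ~15 mm, neck-shaft angle 130 deg, a
    cortical shell in the 200-2000 HU segmentation band over cancellous
    interior in the 100-200 HU band.
    """

    shaft_length: float = 140.0
    shaft_radius: float = 14.0
    neck_length: float = 45.0
    neck_radius: float = 15.0
    head_radius: float = 23.0
    neck_shaft_angle: float = 130.0  # degrees, in (90, 180)
    # regional cortical shell: thick diaphyseal cortex, thin trochanteric
    # band above the lesser-trochanter level, thin neck and head shells --
    # the distribution that gives the femoral neck its clinical fragility
    cortical_thickness: float = 1.5          # neck shell, mm
    shaft_cortical_thickness: float = 6.0
    trochanteric_cortical_thickness: float = 2.0
    head_cortical_thickness: float = 1.0
    cortical_hu: float = 1500.0
    cancellous_hu: float = 150.0
    hu_noise_sd: float = 20.0
    target_edge_length: float = 8.0
    seed: int = 0
    # optional machined waist on the neck: radius dip of given depth (mm)
    # centred at the given fraction of the neck axis (0 = shaft end, 1 = head)
    neck_waist_depth: float = 0.0
    neck_waist_position: float = 0.5
    neck_waist_width: float = 6.0  # Gaussian sigma of the dip, mm

    def validate(self) -> None:
        positive = {
            "shaft_length": self.shaft_length,
            "shaft_radius": self.shaft_radius,
            "neck_length": self.neck_length,
            "neck_radius": self.neck_radius,
            "head_radius": self.head_radius,
            "cortical_thickness": self.cortical_thickness,
            "shaft_cortical_thickness": self.shaft_cortical_thickness,
            "trochanteric_cortical_thickness": self.trochanteric_cortical_thickness,
            "head_cortical_thickness": self.head_cortical_thickness,
            "target_edge_length": self.target_edge_length,
        }
        for name, val in positive.items():
            if not val > 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if not 90.0 < self.neck_shaft_angle < 180.0:
            raise ValueError("neck_shaft_angle must lie in (90, 180) degrees")
        if self.cortical_hu <= self.cancellous_hu:
            raise ValueError("cortical_hu must exceed cancellous_hu")
        if self.hu_noise_sd < 0:
            raise ValueError("hu_noise_sd must be nonnegative")
        if self.cortical_thickness >= self.neck_radius:
            raise ValueError(
                "infeasible geometry: cortical_thickness "
                f"({self.cortical_thickness} mm) >= neck_radius "
                f"({self.neck_radius} mm) leaves no cancellous interior"
            )
        if self.shaft_cortical_thickness >= self.shaft_radius:
            raise ValueError(
                "infeasible geometry: shaft_cortical_thickness >= shaft_radius"
            )
        if self.head_cortical_thickness >= self.head_radius:
            raise ValueError(
                "infeasible geometry: head_cortical_thickness >= head_radius"
            )
        if self.neck_waist_depth >= self.neck_radius:
            raise ValueError("neck_waist_depth must be smaller than neck_radius")


@dataclass
class TetMesh:
    """4-node tetrahedral mesh with per-element HU and named landmarks.

    ``nodes`` are mm coordinates (n, 3); ``tets`` index rows of nodes
    (m, 4) with positive signed volume; ``element_hu`` has one HU value
    per tet.  ``landmarks`` are named 3D points (head_centre,
    greater_trochanter, lesser_trochanter, distal_end_centre, ...);
    ``ground_truth`` optionally stores the constructed anatomy;
    ``metadata`` carries auxiliary scalars such as the head radius.
    """

    nodes: np.ndarray
    tets: np.ndarray
    element_hu: np.ndarray
    landmarks: dict = field(default_factory=dict)
    ground_truth: dict | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.element_hu = np.ascontiguousarray(self.element_hu, dtype=float)

    @property
    def num_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def num_elements(self) -> int:
        return self.tets.shape[0]

    def element_volumes(self) -> np.ndarray:
        """Signed tet volumes (mm^3); positive under the storage convention."""
        p = self.nodes[self.tets]
        return np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0

    def boundary_faces(self) -> np.ndarray:
        """Triangular faces belonging to exactly one tet, as node triples."""
        f = self.tets[:, [[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]]]
        f = f.reshape(-1, 3)
        key = np.sort(f, axis=1)
        _, inv, cnt = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return f[cnt[inv] == 1]

    def surface_nodes(self) -> np.ndarray:
        """Indices of nodes on the mesh boundary."""
        return np.unique(self.boundary_faces())

    def validate(self) -> None:
        if self.element_hu.shape[0] != self.num_elements:
            raise ValueError("element_hu length must equal number of tets")
        if self.tets.min() < 0 or self.tets.max() >= self.num_nodes:
            raise ValueError("tet node index out of range")
        vols = self.element_volumes()
        if np.any(vols <= 0):
            bad = int(np.argmin(vols))
            raise ValueError(f"element {bad} has nonpositive volume {vols[bad]:g}")
        n_comp = self._n_components()
        if n_comp != 1:
            raise ValueError(f"mesh has {n_comp} connected components, expected 1")

    def _n_components(self) -> int:
        i = self.tets[:, [0, 0, 0, 1, 1, 2]].ravel()
        j = self.tets[:, [1, 2, 3, 2, 3, 3]].ravel()
        g = coo_matrix((np.ones_like(i), (i, j)), shape=(self.num_nodes,) * 2)
        n, _ = connected_components(g, directed=False)
        return n


def _fix_orientation(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Swap the last two nodes of negatively oriented tets."""
    p = nodes[tets]
    vol = np.linalg.det(p[:, 1:] - p[:, :1])
    flip = vol < 0
    tets = tets.copy()
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    return tets


def _largest_component(nodes, tets):
    """Restrict to the largest element-connected component and reindex."""
    m = tets.shape[0]
    # elements sharing a node are connected
    node_elem: dict[int, int] = {}
    rows, cols = [], []
    for e in range(m):
        for v in tets[e]:
            if v in node_elem:
                rows.append(node_elem[v])
                cols.append(e)
            else:
                node_elem[v] = e
    g = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
    n, lab = connected_components(g, directed=False)
    if n > 1:
        keep_lab = np.bincount(lab).argmax()
        tets = tets[lab == keep_lab]
    used, inv = np.unique(tets, return_inverse=True)
    return nodes[used], inv.reshape(tets.shape), used


# ----------------------------------------------------------------------------
# implicit proximal-femur solid
# ----------------------------------------------------------------------------

class _FemurSolid:
    """Signed-distance description of shaft U neck U head (negative inside)."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        s = spec
        # shaft axis = +z, distal end at z=0, proximal cap at z=shaft_length
        self.shaft_a = np.array([0.0, 0.0, 0.0])
        self.shaft_b = np.array([0.0, 0.0, s.shaft_length])
        # neck axis leaves the proximal cap centre toward +x (medial);
        # neck-shaft angle is measured between the neck axis oriented away
        # from the head and the proximally oriented shaft axis (+z)
        tilt = np.radians(180.0 - s.neck_shaft_angle)
        self.neck_dir = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
        self.neck_base = self.shaft_b.copy()
        self.head_centre = self.neck_base + s.neck_length * self.neck_dir

    def neck_radius_at(self, t):
        """Neck radius profile along the axis; t in mm from the shaft end."""
        s = self.spec
        r = np.full_like(np.asarray(t, dtype=float), s.neck_radius)
        if s.neck_waist_depth > 0:
            t0 = s.neck_waist_position * s.neck_length
            r = r - s.neck_waist_depth * np.exp(
                -(((np.asarray(t) - t0) / s.neck_waist_width) ** 2)
            )
        return r

    def primitive_sdfs(self, pts: np.ndarray) -> np.ndarray:
        """(3, n) signed distances to shaft, neck and head primitives."""
        pts = np.atleast_2d(pts)
        s = self.spec
        d_shaft = _sdf_capped_cylinder(pts, self.shaft_a, self.shaft_b, s.shaft_radius)
        t = (pts - self.neck_base) @ self.neck_dir
        radial = np.linalg.norm(
            pts - self.neck_base - np.outer(t, self.neck_dir), axis=1
        )
        dr = radial - self.neck_radius_at(np.clip(t, 0.0, s.neck_length))
        dz = np.abs(t - 0.5 * s.neck_length) - 0.5 * s.neck_length
        d_neck = np.minimum(np.maximum(dr, dz), 0.0) + np.linalg.norm(
            np.stack([np.maximum(dr, 0.0), np.maximum(dz, 0.0)]), axis=0
        )
        d_head = np.linalg.norm(pts - self.head_centre, axis=1) - s.head_radius
        return np.stack([d_shaft, d_neck, d_head])

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        return self.primitive_sdfs(pts).min(axis=0)

    def bounds(self):
        s = self.spec
        lo = np.minimum(self.shaft_a - s.shaft_radius,
                        self.head_centre - s.head_radius)
        hi = np.maximum(self.shaft_b + s.shaft_radius,
                        self.head_centre + s.head_radius)
        lo = np.minimum(lo, self.neck_base - s.neck_radius)
        hi = np.maximum(hi, self.neck_base + s.neck_length * self.neck_dir
                        + s.neck_radius)
        return lo, hi


def _sdf_capped_cylinder(pts, a, b, radius):
    axis = b - a
    length = np.linalg.norm(axis)
    u = axis / length
    t = (pts - a) @ u
    radial = np.linalg.norm(pts - a - np.outer(t, u), axis=1)
    dr = radial - radius
    dz = np.abs(t - 0.5 * length) - 0.5 * length
    return np.minimum(np.maximum(dr, dz), 0.0) + np.linalg.norm(
        np.stack([np.maximum(dr, 0.0), np.maximum(dz, 0.0)]), axis=0
    )


def _bcc_lattice(lo, hi, spacing):
    """Corner + body-centre points of a cubic lattice covering [lo, hi]."""
    axes = [np.arange(lo[k] - spacing, hi[k] + 2 * spacing, spacing)
            for k in range(3)]
    corner = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    centre = corner + 0.5 * spacing
    return np.vstack([corner, centre])


def _mesh_implicit(sdf, lo, hi, spacing):
    """Tet mesh of {sdf < 0} from the BCC lattice; max edge == spacing."""
    pts = _bcc_lattice(lo, hi, spacing)
    keep = sdf(pts) < spacing  # points inside or within one cell of surface
    pts = pts[keep]
    tri = Delaunay(pts)
    tets = tri.simplices
    cent = pts[tets].mean(axis=1)
    tets = tets[sdf(cent) < 0.0]
    # drop any non-lattice tets qhull built on the cloud hull (long edges)
    p = pts[tets]
    edges = p[:, [0, 0, 0, 1, 1, 2]] - p[:, [1, 2, 3, 2, 3, 3]]
    emax = np.linalg.norm(edges, axis=2).max(axis=1)
    tets = tets[emax <= spacing * (1.0 + 1e-9)]
    nodes, tets, _ = _largest_component(pts, tets)
    tets = _fix_orientation(nodes, tets)
    vols = np.linalg.det(nodes[tets][:, 1:] - nodes[tets][:, :1]) / 6.0
    keep_vol = vols > 1e-9 * spacing**3
    return nodes, tets[keep_vol]


# ----------------------------------------------------------------------------
# phantom generation
# ----------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> TetMesh:
    """Build the synthetic proximal femur described by ``spec``.

    Returns a single-component tet mesh of shaft U neck U head whose
    elements carry cortical HU within ``cortical_thickness`` of the outer
    surface and cancellous HU inside, plus seeded Gaussian HU noise
    (clamped at 1 HU).  Landmarks, the constructed ground-truth anatomy
    and geometric metadata are attached.
    """
    spec.validate()
    solid = _FemurSolid(spec)
    lo, hi = solid.bounds()
    nodes, tets = _mesh_implicit(solid.sdf, lo, hi, spec.target_edge_length)

    cent = nodes[tets].mean(axis=1)
    prim = solid.primitive_sdfs(cent)
    depth = -prim.min(axis=0)  # distance to outer surface, > 0 inside
    region = prim.argmin(axis=0)  # 0 shaft, 1 neck, 2 head
    shell = np.choose(region, [spec.shaft_cortical_thickness,
                               spec.cortical_thickness,
                               spec.head_cortical_thickness])
    # trochanteric band: shaft region above the lesser-trochanter level
    # keeps the thin metaphyseal cortex of the real proximal femur
    lt_level = spec.shaft_length - 25.0
    shell = np.where((region == 0) & (cent[:, 2] > lt_level),
                     spec.trochanteric_cortical_thickness, shell)
    hu = np.where(depth <= shell,
                  spec.cortical_hu, spec.cancellous_hu).astype(float)
    if spec.hu_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.hu_noise_sd, size=hu.shape)
    hu = np.maximum(hu, 1.0)

    s = spec
    landmarks = {
        "head_centre": solid.head_centre.copy(),
        "greater_trochanter": np.array([-s.shaft_radius, 0.0, s.shaft_length]),
        "lesser_trochanter": np.array([s.shaft_radius, 0.0, s.shaft_length - 25.0]),
        "distal_end_centre": np.array([0.0, 0.0, 0.0]),
    }
    ground_truth = {
        "neck_shaft_angle": float(s.neck_shaft_angle),
        "neck_axis": solid.neck_dir.copy(),       # oriented toward the head
        "neck_point": solid.neck_base.copy(),
        "shaft_axis": np.array([0.0, 0.0, 1.0]),  # oriented proximally
        "shaft_point": np.array([0.0, 0.0, 0.0]),
        "waist_position_mm": (s.neck_waist_position * s.neck_length
                              if s.neck_waist_depth > 0 else None),
    }
    metadata = {
        "head_radius": s.head_radius,
        "neck_radius": s.neck_radius,
        "shaft_radius": s.shaft_radius,
        "neck_length": s.neck_length,
        "shaft_length": s.shaft_length,
        "target_edge_length": s.target_edge_length,
        "kind": "femur_phantom",
    }
    mesh = TetMesh(nodes, tets, hu, landmarks, ground_truth, metadata)
    mesh.validate()
    return mesh


# ----------------------------------------------------------------------------
# analytic fixtures
# ----------------------------------------------------------------------------

def generate_bar_fixture(length: float, cross_section_side: float,
                         edge_length: float, hu: float) -> TetMesh:
    """Rectangular bar along +x, square cross-section, uniform HU.

    Structured mesh: each grid cube is split into six tets (Kuhn split),
    so the summed element volume equals length * side^2 exactly.
    Landmarks mark the centres of the two end faces.
    """
    if length <= 0 or cross_section_side <= 0 or edge_length <= 0:
        raise ValueError("bar dimensions must be positive")
    if edge_length > min(length, cross_section_side):
        raise ValueError("edge_length exceeds the smallest bar dimension")
    h = edge_length / np.sqrt(3.0)  # cube diagonal <= edge_length
    dims = (length, cross_section_side, cross_section_side)
    divs = [max(1, int(np.ceil(d / h))) for d in dims]
    axes = [np.linspace(0.0, d, n + 1) for d, n in zip(dims, divs)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    nodes = grid.reshape(-1, 3)
    nx, ny, nz = (len(a) for a in axes)

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    tets = []
    kuhn = [(0, 1, 3, 7), (0, 1, 5, 7), (0, 2, 3, 7),
            (0, 2, 6, 7), (0, 4, 5, 7), (0, 4, 6, 7)]
    for i in range(divs[0]):
        for j in range(divs[1]):
            for k in range(divs[2]):
                corner = [nid(i + a, j + b, k + c)
                          for a in (0, 1) for b in (0, 1) for c in (0, 1)]
                # corner order: bit pattern (a b c) -> index a*4 + b*2 + c
                for t in kuhn:
                    tets.append([corner[v] for v in t])
    tets = _fix_orientation(nodes, np.array(tets, dtype=np.int64))

    cy = cz = cross_section_side / 2.0
    landmarks = {
        "end_min": np.array([0.0, cy, cz]),
        "end_max": np.array([length, cy, cz]),
    }
    metadata = {"kind": "bar", "length": length, "side": cross_section_side,
                "area": cross_section_side**2}
    mesh = TetMesh(nodes, tets, np.full(len(tets), float(hu)),
                   landmarks, None, metadata)
    mesh.validate()
    return mesh


def _split_prism(prism):
    """Split a 6-node prism (bottom a,b,c / top d,e,f) into 3 tets.

    The diagonal of every quadrilateral face passes through the face's
    smallest global node index, so adjacent prisms triangulate shared
    faces identically (Dompierre-style indexed subdivision).
    """
    rot = lambda p: [p[1], p[2], p[0], p[4], p[5], p[3]]
    mirror = lambda p: [p[3], p[5], p[4], p[0], p[2], p[1]]
    perms = []
    q = list(prism)
    for _ in range(3):
        perms.append(q)
        perms.append(mirror(q))
        q = rot(q)
    p = min(perms, key=lambda pp: pp[0])
    if min(p[1], p[5]) < min(p[2], p[4]):
        return [(p[0], p[1], p[2], p[5]), (p[0], p[1], p[5], p[4]),
                (p[0], p[4], p[5], p[3])]
    return [(p[0], p[1], p[2], p[4]), (p[0], p[4], p[2], p[5]),
            (p[0], p[4], p[5], p[3])]


def generate_cylinder_fixture(radius: float, length: float,
                              edge_length: float, hu: float) -> TetMesh:
    """Circular cylinder along +z, uniform HU, via extruded disc mesh.

    The disc is meshed with concentric rings of points and 2D Delaunay;
    layers are extruded into prisms split into tets with consistent
    diagonals.  The mesh volume equals the faceted-polygon prism volume,
    within O((edge/radius)^2) of pi r^2 L.
    """
    if radius <= 0 or length <= 0 or edge_length <= 0:
        raise ValueError("cylinder dimensions must be positive")
    if edge_length > min(radius, length):
        raise ValueError("edge_length exceeds the smallest cylinder dimension")
    h = edge_length / np.sqrt(2.0)
    n_ring = max(1, int(np.ceil(radius / h)))
    pts2d = [np.zeros((1, 2))]
    for k in range(1, n_ring + 1):
        r_k = radius * k / n_ring
        n_k = max(6, int(np.ceil(2 * np.pi * r_k / h)))
        th = 2 * np.pi * (np.arange(n_k) + 0.5 * (k % 2)) / n_k
        pts2d.append(np.stack([r_k * np.cos(th), r_k * np.sin(th)], axis=1))
    pts2d = np.vstack(pts2d)
    tri2d = Delaunay(pts2d).simplices
    npts = pts2d.shape[0]

    n_lay = max(1, int(np.ceil(length / h)))
    zs = np.linspace(0.0, length, n_lay + 1)
    nodes = np.concatenate(
        [np.column_stack([pts2d, np.full(npts, z)]) for z in zs]
    )
    tets = []
    for lay in range(n_lay):
        base, top = lay * npts, (lay + 1) * npts
        for (a, b, c) in tri2d:
            tets.extend(_split_prism(
                [base + a, base + b, base + c, top + a, top + b, top + c]
            ))
    tets = _fix_orientation(nodes, np.array(tets, dtype=np.int64))
    landmarks = {
        "end_min": np.array([0.0, 0.0, 0.0]),
        "end_max": np.array([0.0, 0.0, length]),
    }
    metadata = {"kind": "cylinder", "radius": radius, "length": length}
    mesh = TetMesh(nodes, tets, np.full(len(tets), float(hu)),
                   landmarks, None, metadata)
    mesh.validate()
    return mesh


# ----------------------------------------------------------------------------
# mesh I/O: legacy ASCII VTK (+ CSV fallback dialect)
# ----------------------------------------------------------------------------

def save_vtk(mesh: TetMesh, path, cell_data: dict | None = None,
             point_data: dict | None = None) -> None:
    """Write a legacy ASCII VTK unstructured grid.

    Element HU is stored as cell data ``hu``; landmarks, ground truth and
    metadata are serialised as JSON on the VTK title line (legacy VTK
    reserves it for a free-form description).  Extra per-cell scalar
    arrays and per-point vector arrays may be supplied.
    """
    meta = {
        "landmarks": {k: list(map(float, v)) for k, v in mesh.landmarks.items()},
        "ground_truth": _jsonify(mesh.ground_truth),
        "metadata": _jsonify(mesh.metadata),
    }
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(json.dumps(meta, separators=(",", ":")) + "\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.num_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.17g")
        m = mesh.num_elements
        fh.write(f"CELLS {m} {5 * m}\n")
        np.savetxt(fh, np.hstack([np.full((m, 1), 4, dtype=np.int64), mesh.tets]),
                   fmt="%d")
        fh.write(f"CELL_TYPES {m}\n")
        np.savetxt(fh, np.full(m, 10, dtype=np.int64), fmt="%d")
        fh.write(f"CELL_DATA {m}\n")
        fh.write("SCALARS hu double 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, mesh.element_hu, fmt="%.17g")
        for name, arr in (cell_data or {}).items():
            arr = np.asarray(arr, dtype=float)
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr, fmt="%.17g")
        if point_data:
            fh.write(f"POINT_DATA {mesh.num_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float)
                fh.write(f"VECTORS {name} double\n")
                np.savetxt(fh, arr.reshape(mesh.num_nodes, 3), fmt="%.17g")


def load_vtk(path) -> TetMesh:
    """Read a mesh written by :func:`save_vtk` (legacy ASCII VTK, tets only)."""
    with open(path) as fh:
        tokens_meta = fh.readline()
        title = fh.readline().strip()
        body = fh.read().split()
    try:
        meta = json.loads(title)
    except json.JSONDecodeError:
        meta = {"landmarks": {}, "ground_truth": None, "metadata": {}}
    it = iter(body)
    nodes = tets = hu = None
    for tok in it:
        if tok == "POINTS":
            n = int(next(it)); next(it)
            nodes = np.fromiter(
                (float(next(it)) for _ in range(3 * n)), float
            ).reshape(n, 3)
        elif tok == "CELLS":
            m = int(next(it)); total = int(next(it))
            raw = np.fromiter((int(next(it)) for _ in range(total)), np.int64)
            tets = raw.reshape(m, 5)[:, 1:]
        elif tok == "SCALARS":
            name = next(it)
            next(it), next(it)  # type, n components
            nvals = tets.shape[0]
            if next(it) != "LOOKUP_TABLE":
                raise ValueError("expected LOOKUP_TABLE after SCALARS header")
            next(it)
            vals = np.fromiter((float(next(it)) for _ in range(nvals)), float)
            if name == "hu":
                hu = vals
    if nodes is None or tets is None or hu is None:
        raise ValueError(f"{path} is not a femrisk VTK mesh")
    landmarks = {k: np.array(v) for k, v in meta.get("landmarks", {}).items()}
    gt = meta.get("ground_truth")
    if gt:
        gt = {k: (np.array(v) if isinstance(v, list) else v) for k, v in gt.items()}
    return TetMesh(nodes, tets, hu, landmarks, gt, meta.get("metadata", {}))


def save_csv(mesh: TetMesh, prefix) -> None:
    """CSV fallback dialect: <prefix>_nodes.csv, <prefix>_elements.csv,
    <prefix>_landmarks.csv."""
    np.savetxt(f"{prefix}_nodes.csv", mesh.nodes, delimiter=",",
               header="x_mm,y_mm,z_mm", comments="", fmt="%.17g")
    elems = np.column_stack([mesh.tets, mesh.element_hu])
    np.savetxt(f"{prefix}_elements.csv", elems, delimiter=",",
               header="n0,n1,n2,n3,hu", comments="",
               fmt=["%d"] * 4 + ["%.17g"])
    with open(f"{prefix}_landmarks.csv", "w") as fh:
        fh.write("name,x_mm,y_mm,z_mm\n")
        for k, v in mesh.landmarks.items():
            fh.write(f"{k},{float(v[0])!r},{float(v[1])!r},{float(v[2])!r}\n")


def load_csv(prefix) -> TetMesh:
    nodes = np.loadtxt(f"{prefix}_nodes.csv", delimiter=",", skiprows=1)
    elems = np.loadtxt(f"{prefix}_elements.csv", delimiter=",", skiprows=1)
    landmarks = {}
    try:
        with open(f"{prefix}_landmarks.csv") as fh:
            next(fh)
            for line in fh:
                name, x, y, z = line.strip().split(",")
                landmarks[name] = np.array([float(x), float(y), float(z)])
    except FileNotFoundError:
        warnings.warn("no landmarks file found; landmarks empty")
    return TetMesh(nodes.reshape(-1, 3), elems[:, :4].astype(np.int64),
                   elems[:, 4], landmarks)


def _jsonify(obj):
    if obj is None:
        return None
    out = {}
    for k, v in obj.items():
        if isinstance(v, np.ndarray):
            out[k] = [float(x) for x in v]
        else:
            out[k] = v
    return out
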