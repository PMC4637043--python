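"""Linear elastostatic finite-element analysis on tetrahedral femur meshes.

Constant-strain 4-node tets in the mm-N-MPa unit system (1 MPa = 1 N/mm^2,
energies in N*mm).  Two physiological load cases are provided:

* single-leg stance -- joint load of 2.5 x body weight distributed over the
  femoral-head surface along the shaft axis, distal end fully fixed;
* sideways fall -- trochanteric impact F = 8.25 * w * sqrt(h/170) N (w body
  weight in N, h height in cm) applied perpendicular to the shaft axis in
  the neck-shaft plane, distal end fixed, femoral-head surface held in the
  loading direction only.

The assembled system K d = f is solved with a sparse direct factorisation;
oblique single-direction constraints are imposed with Lagrange multipliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import DEFAULT_NU, MaterialTable, elasticity_matrix
from .phantom import TetMesh

__all__ = [
    "STANCE_FACTOR",
    "IMPACT_FACTOR",
    "REFERENCE_HEIGHT_CM",
    "LoadCase",
    "FESolution",
    "SingularSystemError",
    "stance_force",
    "impact_force",
    "build_load_case",
    "face_force_distribution",
    "solve",
    "von_mises_stress",
    "von_mises_strain",
    "von_mises_fields",
]

STANCE_FACTOR = 2.5        # stance joint load / body weight
IMPACT_FACTOR = 8.25       # fall impact load / body weight at reference height
REFERENCE_HEIGHT_CM = 170.0

# Voigt order (xx, yy, zz, xy, yz, zx), engineering shear strains
_VOIGT_PAIRS = [(0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (2, 0)]


class SingularSystemError(RuntimeError):
    """The constrained stiffness matrix still has rigid-body modes."""


def stance_force(w: float) -> float:
    """Single-leg-stance joint force (N) for body weight ``w`` (N)."""
    if w <= 0:
        raise ValueError("body weight must be positive")
    return STANCE_FACTOR * w


def impact_force(w: float, h: float) -> float:
    """Sideways-fall trochanteric impact force (N).

    ``w`` body weight in N, ``h`` subject height in cm; scales with the
    square root of height relative to the 170 cm reference.
    """
    if w <= 0 or h <= 0:
        raise ValueError("body weight and height must be positive")
    return IMPACT_FACTOR * w * np.sqrt(h / REFERENCE_HEIGHT_CM)


@dataclass
class LoadCase:
    """Nodal loads and kinematic constraints for one configuration."""

    configuration: str                 # "stance" | "fall" | free-form label
    body_weight_w: float | None       # N
    height_h: float | None            # cm
    total_force: float                # N
    loaded_nodes: np.ndarray          # node indices
    nodal_forces: np.ndarray          # (k, 3) N, one row per loaded node
    fixed_nodes: np.ndarray           # fully fixed node indices
    direction_constraints: list = field(default_factory=list)
    # list of (node_index, unit direction): u . n = 0 at that node

    def force_vector(self, num_nodes: int) -> np.ndarray:
        f = np.zeros((num_nodes, 3))
        np.add.at(f, self.loaded_nodes, self.nodal_forces)
        return f.ravel()

    def validate(self) -> None:
        total = self.nodal_forces.sum(axis=0)
        mag = np.linalg.norm(total)
        if self.total_force > 0 and abs(mag - self.total_force) > 1e-9 * self.total_force:
            raise ValueError("nodal forces do not sum to the total force")
        if np.intersect1d(self.fixed_nodes, self.loaded_nodes).size:
            raise ValueError("fixed and loaded node sets must be disjoint")


def _shaft_axis_of(mesh: TetMesh, axes=None) -> tuple[np.ndarray, np.ndarray]:
    """Proximally oriented shaft axis and a point on it."""
    if axes is not None:
        return np.asarray(axes.shaft_axis, float), np.asarray(axes.shaft_point, float)
    if mesh.ground_truth and "shaft_axis" in mesh.ground_truth:
        return (np.asarray(mesh.ground_truth["shaft_axis"], float),
                np.asarray(mesh.ground_truth["shaft_point"], float))
    from . import anatomy  # lazy: anatomy depends on mesh slicing only
    est = anatomy.estimate_axes(mesh)
    return est.shaft_axis, est.shaft_point


def build_load_case(mesh: TetMesh, configuration: str, w: float,
                    h: float | None = None, axes=None,
                    head_capture: float = 1.05,
                    distal_tolerance: float = 5.0,
                    trochanter_capture: float = 12.0) -> LoadCase:
    """Construct stance or fall boundary conditions from mesh landmarks.

    Node sets are selected geometrically: femoral-head surface nodes within
    ``head_capture`` x head radius of the head centre, trochanteric surface
    nodes within ``trochanter_capture`` mm of the greater-trochanter
    landmark, and distal nodes within ``distal_tolerance`` mm of the distal
    end plane.  The total force is split equally over the loaded nodes.
    """
    if configuration not in ("stance", "fall"):
        raise ValueError(f"unknown configuration {configuration!r}")
    lm = mesh.landmarks
    for need in ("head_centre", "distal_end_centre"):
        if need not in lm:
            raise ValueError(f"mesh landmark {need!r} required")
    shaft_dir, _ = _shaft_axis_of(mesh, axes)
    shaft_dir = shaft_dir / np.linalg.norm(shaft_dir)

    surf = mesh.surface_nodes()
    head_c = np.asarray(lm["head_centre"], float)
    head_r = float(mesh.metadata.get("head_radius", 0.0))
    if head_r <= 0.0:
        if axes is not None and getattr(axes, "head_radius", 0):
            head_r = float(axes.head_radius)
        else:
            raise ValueError("head radius unknown: provide mesh metadata or axes")
    head_nodes = surf[np.linalg.norm(mesh.nodes[surf] - head_c, axis=1)
                      <= head_capture * head_r]

    distal_c = np.asarray(lm["distal_end_centre"], float)
    t = (mesh.nodes - distal_c) @ shaft_dir
    distal_nodes = np.where(t <= t.min() + distal_tolerance)[0]

    if configuration == "stance":
        total = stance_force(w)
        direction = -shaft_dir  # joint load pushes distally along the shaft
        loaded = np.setdiff1d(head_nodes, distal_nodes)
        if loaded.size == 0:
            raise ValueError("empty femoral-head node selection")
        forces = np.tile(total * direction / loaded.size, (loaded.size, 1))
        return LoadCase("stance", w, h, total, loaded, forces,
                        distal_nodes, [])

    if h is None:
        raise ValueError("fall configuration requires subject height h (cm)")
    if "greater_trochanter" not in lm:
        raise ValueError("mesh landmark 'greater_trochanter' required")
    total = impact_force(w, h)
    # medial direction: component of (head centre - shaft axis) normal to
    # the shaft axis, i.e. perpendicular impact within the neck-shaft plane
    medial = head_c - distal_c
    medial = medial - (medial @ shaft_dir) * shaft_dir
    norm = np.linalg.norm(medial)
    if norm < 1e-9:
        raise ValueError("head centre lies on the shaft axis; fall direction undefined")
    medial /= norm
    gt = np.asarray(lm["greater_trochanter"], float)
    troch_nodes = surf[np.linalg.norm(mesh.nodes[surf] - gt, axis=1)
                       <= trochanter_capture]
    loaded = np.setdiff1d(troch_nodes, distal_nodes)
    if loaded.size == 0:
        raise ValueError("empty greater-trochanter node selection")
    forces = np.tile(total * medial / loaded.size, (loaded.size, 1))
    head_only = np.setdiff1d(head_nodes, np.concatenate([distal_nodes, loaded]))
    constraints = [(int(n), medial.copy()) for n in head_only]
    return LoadCase("fall", w, h, total, loaded, forces,
                    distal_nodes, constraints)


def face_force_distribution(mesh: TetMesh, node_set: np.ndarray,
                            total_vector: np.ndarray) -> np.ndarray:
    """Consistent (area-weighted) nodal forces for a uniform surface traction.

    Each boundary triangle whose three corners all lie in ``node_set``
    contributes a third of its area to each corner, so edge and corner
    nodes receive proportionally smaller shares than interior nodes.
    Used by the analytic fixtures where the exact solution assumes a
    uniform traction; the physiological load cases use an equal split.
    """
    node_set = np.asarray(node_set, dtype=int)
    members = np.zeros(mesh.num_nodes, dtype=bool)
    members[node_set] = True
    weights = np.zeros(mesh.num_nodes)
    for tri in mesh.boundary_faces():
        if members[tri].all():
            p = mesh.nodes[tri]
            area = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
            weights[tri] += area / 3.0
    w = weights[node_set]
    if w.sum() <= 0:
        raise ValueError("node set spans no boundary faces")
    return np.outer(w / w.sum(), np.asarray(total_vector, float))


@dataclass
class FESolution:
    """Displacements and recovered element fields of one solved case."""

    nodal_displacements: np.ndarray      # (n, 3) mm
    element_strain: np.ndarray           # (m, 3, 3) tensor strain
    element_stress: np.ndarray           # (m, 3, 3) MPa
    element_energy_density: np.ndarray   # (m,) N*mm/mm^3
    element_von_mises_stress: np.ndarray
    element_von_mises_strain: np.ndarray
    total_strain_energy: float           # N*mm
    applied_forces: np.ndarray           # (n, 3) N
    load: LoadCase
    mesh: TetMesh = field(repr=False, default=None)
    materials: MaterialTable = field(repr=False, default=None)

    @property
    def clapeyron_work(self) -> float:
        """Half the work of applied nodal forces, 0.5 f.d (N*mm)."""
        return 0.5 * float(
            self.applied_forces.ravel() @ self.nodal_displacements.ravel()
        )


def _element_b_matrices(nodes: np.ndarray, tets: np.ndarray):
    """Per-element volumes and strain-displacement matrices B (6 x 12)."""
    p = nodes[tets]                       # (m, 4, 3)
    jac = p[:, 1:] - p[:, :1]             # rows: edge vectors
    det = np.linalg.det(jac)
    if np.any(det <= 0):
        bad = int(np.argmin(det))
        raise ValueError(f"element {bad} has nonpositive volume {det[bad] / 6.0:g}")
    inv = np.linalg.inv(jac)
    grads = np.empty((tets.shape[0], 4, 3))
    grads[:, 1:, :] = np.transpose(inv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    m = tets.shape[0]
    b = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        b[:, 0, c] = gx
        b[:, 1, c + 1] = gy
        b[:, 2, c + 2] = gz
        b[:, 3, c] = gy; b[:, 3, c + 1] = gx
        b[:, 4, c + 1] = gz; b[:, 4, c + 2] = gy
        b[:, 5, c] = gz; b[:, 5, c + 2] = gx
    return det / 6.0, b


def solve(mesh: TetMesh, materials: MaterialTable, load: LoadCase,
          check_residual: float = 1e-8) -> FESolution:
    """Assemble and solve K d = f, then recover element fields.

    Fully fixed nodes and single-direction constraints (u . n = 0) are
    imposed with Lagrange multipliers on the symmetric system.  Raises
    :class:`SingularSystemError` when the constraints leave rigid-body
    modes, naming the unconstrained mode count.
    """
    load.validate()
    n = mesh.num_nodes
    ndof = 3 * n
    vols, b = _element_b_matrices(mesh.nodes, mesh.tets)
    e_elem = materials.element_E
    nu = materials.nu
    d_unit = elasticity_matrix(1.0, nu)
    # k_e = V_e * E_e * B^T D1 B
    db = np.einsum("ij,mjk->mik", d_unit, b)
    ke = np.einsum("mji,mjk->mik", b, db) * (vols * e_elem)[:, None, None]

    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(-1, 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    k = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()

    # constraint rows
    c_rows, c_cols, c_vals = [], [], []
    r = 0
    for node in np.asarray(load.fixed_nodes, dtype=int):
        for ax in range(3):
            c_rows.append(r); c_cols.append(3 * node + ax); c_vals.append(1.0)
            r += 1
    for node, direction in load.direction_constraints:
        direction = np.asarray(direction, float)
        direction = direction / np.linalg.norm(direction)
        for ax in range(3):
            c_rows.append(r); c_cols.append(3 * node + ax)
            c_vals.append(direction[ax])
        r += 1
    if r < 6:
        raise SingularSystemError(
            f"system is under-constrained: at least {6 - r} rigid-body "
            "mode(s) remain (fewer than 6 constraint equations)"
        )
    c = sp.coo_matrix((c_vals, (c_rows, c_cols)), shape=(r, ndof)).tocsr()

    f = load.force_vector(n)
    scale = k.diagonal().max()
    aug = sp.bmat([[k, c.T * scale], [c * scale, None]], format="csc")
    rhs = np.concatenate([f, np.zeros(r)])
    with np.errstate(all="ignore"):
        sol = spla.spsolve(aug, rhs)
    d = sol[:ndof]
    fnorm = np.linalg.norm(rhs)
    resid = np.linalg.norm(aug @ sol - rhs)
    if not np.all(np.isfinite(d)) or (fnorm > 0 and resid > check_residual * fnorm):
        n_modes = _count_rigid_modes(k, c)
        raise SingularSystemError(
            f"singular stiffness system: {n_modes} unconstrained rigid-body "
            f"mode(s) detected (relative residual {resid / max(fnorm, 1e-300):.2e})"
        )

    disp = d.reshape(n, 3)
    de = d[dofs]                                   # (m, 12)
    strain_v = np.einsum("mij,mj->mi", b, de)      # engineering Voigt
    stress_v = np.einsum("ij,mj->mi", d_unit, strain_v) * e_elem[:, None]
    energy_density = 0.5 * np.einsum("mi,mi->m", stress_v, strain_v)
    total_energy = float((vols * energy_density).sum())

    strain_t = _voigt_to_tensor(strain_v, engineering=True)
    stress_t = _voigt_to_tensor(stress_v, engineering=False)
    vm_s = von_mises_stress(stress_t)
    vm_e = von_mises_strain(strain_t, nu)

    return FESolution(disp, strain_t, stress_t, energy_density, vm_s, vm_e,
                      total_energy, f.reshape(n, 3), load, mesh, materials)


def _count_rigid_modes(k, c) -> int:
    """Estimate the number of near-zero modes of the constrained system."""
    try:
        kc = (k + c.T @ c * k.diagonal().max()).tocsc()
        vals = spla.eigsh(kc, k=6, sigma=0, which="LM",
                          return_eigenvectors=False, tol=1e-6)
        ref = k.diagonal().max()
        return int(np.sum(np.abs(vals) < 1e-8 * ref))
    except Exception:
        return 6


def _voigt_to_tensor(v, engineering: bool) -> np.ndarray:
    m = v.shape[0]
    t = np.zeros((m, 3, 3))
    half = 0.5 if engineering else 1.0
    t[:, 0, 0], t[:, 1, 1], t[:, 2, 2] = v[:, 0], v[:, 1], v[:, 2]
    t[:, 0, 1] = t[:, 1, 0] = half * v[:, 3]
    t[:, 1, 2] = t[:, 2, 1] = half * v[:, 4]
    t[:, 2, 0] = t[:, 0, 2] = half * v[:, 5]
    return t


def von_mises_stress(stress: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress from (m, 3, 3) stress tensors (MPa)."""
    stress = np.atleast_3d(stress).reshape(-1, 3, 3)
    tr = np.trace(stress, axis1=1, axis2=2) / 3.0
    dev = stress - tr[:, None, None] * np.eye(3)
    return np.sqrt(1.5 * np.einsum("mij,mij->m", dev, dev))


def von_mises_strain(strain: np.ndarray, nu: float = DEFAULT_NU) -> np.ndarray:
    """Equivalent von Mises strain from principal strains.

    Uses the principal-strain form 1/(1+nu') * sqrt(0.5 * sum of squared
    principal differences) with the effective Poisson ratio nu' equal to
    the material value.
    """
    strain = np.atleast_3d(strain).reshape(-1, 3, 3)
    e = np.linalg.eigvalsh(strain)
    d01 = e[:, 0] - e[:, 1]
    d12 = e[:, 1] - e[:, 2]
    d20 = e[:, 2] - e[:, 0]
    return np.sqrt(0.5 * (d01**2 + d12**2 + d20**2)) / (1.0 + nu)


def von_mises_fields(solution: FESolution,
                     nu: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(von Mises stress, von Mises strain) per element of a solution."""
    if nu is None:
        nu = solution.materials.nu if solution.materials else DEFAULT_NU
    return (von_mises_stress(solution.element_stress),
            von_mises_strain(solution.element_strain, nu))
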