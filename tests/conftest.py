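"""Shared fixtures: default phantom, solved load cases, analytic bar."""

import numpy as np
import pytest

from femrisk import (PhantomSpec, bin_materials, build_load_case,
                     estimate_axes, find_critical_sections,
                     generate_bar_fixture, generate_phantom, solve)
from femrisk import materials as mat
from femrisk.fea import LoadCase, face_force_distribution

BODY_WEIGHT_N = 700.0
HEIGHT_CM = 170.0


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def default_materials(default_phantom):
    return bin_materials(default_phantom.element_hu, 50)


@pytest.fixture(scope="session")
def default_axes(default_phantom):
    return estimate_axes(default_phantom)


@pytest.fixture(scope="session")
def default_sections(default_phantom, default_axes):
    return find_critical_sections(default_phantom, default_axes)


@pytest.fixture(scope="session")
def solved_cases(default_phantom, default_materials, default_axes):
    """Stance and fall FE solutions on the default phantom."""
    out = {}
    for cfg in ("stance", "fall"):
        load = build_load_case(default_phantom, cfg, BODY_WEIGHT_N, HEIGHT_CM,
                               axes=default_axes)
        out[cfg] = solve(default_phantom, default_materials, load)
    return out


def hu_for_modulus(e_mpa: float) -> float:
    """HU value whose calibrated modulus equals ``e_mpa`` exactly."""
    rho = (e_mpa / mat.MODULUS_COEFF) ** (1.0 / mat.MODULUS_EXP)
    return (rho - mat.ASH_INTERCEPT) / mat.ASH_SLOPE


def axial_bar_case(bar, force_n: float) -> LoadCase:
    """Uniform-traction axial tension with the minimal constraint set.

    The left face is held axially, one corner pinned laterally and one
    further node in z, so the exact uniaxial state (with free lateral
    contraction) is representable and the closed forms hold exactly.
    """
    x, y, z = bar.nodes.T
    left = np.where(x < 1e-9)[0]
    right = np.where(x > bar.metadata["length"] - 1e-9)[0]
    forces = face_force_distribution(bar, right, [force_n, 0.0, 0.0])
    cons = [(int(n), np.array([1.0, 0.0, 0.0])) for n in left]
    side = bar.metadata["side"]
    corner = int(np.where((x < 1e-9) & (y < 1e-9) & (z < 1e-9))[0][0])
    other = int(np.where((x < 1e-9) & (np.abs(y - side) < 1e-9)
                         & (z < 1e-9))[0][0])
    cons += [(corner, np.array([0.0, 1.0, 0.0])),
             (corner, np.array([0.0, 0.0, 1.0])),
             (other, np.array([0.0, 0.0, 1.0]))]
    return LoadCase("axial", None, None, force_n, right, forces,
                    np.array([], dtype=int), cons)


@pytest.fixture(scope="session")
def bar_assets():
    """100 x 10 x 10 mm bar with E = 1000 MPa, 1000 N axial tension."""
    bar = generate_bar_fixture(100.0, 10.0, 5.0, hu_for_modulus(1000.0))
    table = bin_materials(bar.element_hu, 50)
    load = axial_bar_case(bar, 1000.0)
    solution = solve(bar, table, load)
    return {"mesh": bar, "materials": table, "load": load,
            "solution": solution, "F": 1000.0, "A": 100.0, "L": 100.0,
            "E": 1000.0}
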