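"""Bone material laws: HU -> ash density -> stiffness and strength.

CT attenuation (Hounsfield Units) is mapped to ash density by a linear
calibration, and ash density to Young's modulus and yield stress by
empirical power laws for human femoral bone:

    rho_ash = 0.04162 + 0.000854 * HU      [g/cm^3]
    E       = 10500 * rho_ash ** 2.29      [MPa]
    sigma_Y = 116   * rho_ash ** 2.03      [MPa]

Poisson's ratio is held constant (nu = 0.4).  Elements are grouped into
discrete material bins so the inhomogeneous field is represented by a
manageable number of (E, sigma_Y) pairs, as is customary in QCT-based
finite-element modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ASH_INTERCEPT",
    "ASH_SLOPE",
    "MODULUS_COEFF",
    "MODULUS_EXP",
    "YIELD_COEFF",
    "YIELD_EXP",
    "DEFAULT_NU",
    "DEFAULT_N_BINS",
    "DENSITY_CLAMP",
    "MaterialBin",
    "MaterialTable",
    "ash_density_from_hu",
    "young_modulus",
    "yield_stress",
    "bin_materials",
    "elasticity_matrix",
]

# calibration / power-law constants (femoral bone, mm-N-MPa unit system)
ASH_INTERCEPT = 0.04162  # g/cm^3 at 0 HU
ASH_SLOPE = 0.000854     # g/cm^3 per HU
MODULUS_COEFF = 10500.0  # MPa at unit ash density
MODULUS_EXP = 2.29
YIELD_COEFF = 116.0      # MPa at unit ash density
YIELD_EXP = 2.03
DEFAULT_NU = 0.4
DEFAULT_N_BINS = 50
# lower clamp: the calibration goes nonpositive below ~ -49 HU (air/marrow);
# stiffness must stay positive, bone segmentation never reaches this regime
DENSITY_CLAMP = 0.01     # g/cm^3


def ash_density_from_hu(hu):
    """Ash density (g/cm^3) from a HU value or array, clamped at DENSITY_CLAMP."""
    hu = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU values must be finite")
    rho = ASH_INTERCEPT + ASH_SLOPE * hu
    rho = np.maximum(rho, DENSITY_CLAMP)
    return rho if rho.ndim else float(rho)


def young_modulus(rho_ash):
    """Young's modulus (MPa) from ash density (g/cm^3)."""
    rho = np.asarray(rho_ash, dtype=float)
    if np.any(rho <= 0.0):
        raise ValueError("ash density must be positive")
    e = MODULUS_COEFF * rho ** MODULUS_EXP
    return e if e.ndim else float(e)


def yield_stress(rho_ash):
    """Yield stress (MPa) from ash density (g/cm^3)."""
    rho = np.asarray(rho_ash, dtype=float)
    if np.any(rho <= 0.0):
        raise ValueError("ash density must be positive")
    s = YIELD_COEFF * rho ** YIELD_EXP
    return s if s.ndim else float(s)


@dataclass(frozen=True)
class MaterialBin:
    """One discrete material group: representative density and derived laws."""

    bin_id: int
    representative_ash_density: float  # g/cm^3, mean over member elements
    E: float                           # MPa
    sigma_Y: float                     # MPa
    nu: float = DEFAULT_NU

    def __post_init__(self):
        if self.E <= 0 or self.sigma_Y <= 0:
            raise ValueError("material bin must have positive E and sigma_Y")

    @property
    def yield_energy_density(self) -> float:
        """Yield strain-energy density sigma_Y^2 / (2 E), N*mm/mm^3."""
        return self.sigma_Y**2 / (2.0 * self.E)


@dataclass
class MaterialTable:
    """Per-element material assignment through discrete density bins."""

    bins: list[MaterialBin]
    element_bin: np.ndarray  # bin index per element
    n_bins: int              # requested bin count (>= number of nonempty bins)
    element_ash_density: np.ndarray = field(repr=False, default=None)

    @property
    def element_E(self) -> np.ndarray:
        return np.array([b.E for b in self.bins])[self.element_bin]

    @property
    def element_sigma_y(self) -> np.ndarray:
        return np.array([b.sigma_Y for b in self.bins])[self.element_bin]

    @property
    def element_yield_energy_density(self) -> np.ndarray:
        return np.array([b.yield_energy_density for b in self.bins])[self.element_bin]

    @property
    def nu(self) -> float:
        return self.bins[0].nu

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("bin_id,density_g_cm3,E_MPa,sigma_Y_MPa,nu\n")
            for b in self.bins:
                fh.write(
                    f"{b.bin_id},{b.representative_ash_density!r},"
                    f"{b.E!r},{b.sigma_Y!r},{b.nu!r}\n"
                )


def bin_materials(element_hu, n_bins: int = DEFAULT_N_BINS,
                  nu: float = DEFAULT_NU) -> MaterialTable:
    """Group elements into <= ``n_bins`` material bins on ash density.

    Bins are equal-width intervals on ash density spanning the observed
    [min, max]; each nonempty bin's representative density is the mean
    density of its member elements, from which E and sigma_Y follow.
    When ``n_bins`` meets or exceeds the number of distinct densities,
    every distinct density receives its own bin, so the binned per-element
    stiffness coincides with the unbinned one.
    """
    hu = np.asarray(element_hu, dtype=float)
    if hu.size == 0:
        raise ValueError("cannot bin an empty element set")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rho = np.asarray(ash_density_from_hu(hu))

    uniq = np.unique(rho)
    if n_bins >= uniq.size:
        # exact mode: one bin per distinct density
        idx = np.searchsorted(uniq, rho)
        reps = uniq
    else:
        lo, hi = float(uniq[0]), float(uniq[-1])
        edges = np.linspace(lo, hi, n_bins + 1)
        idx = np.clip(np.searchsorted(edges, rho, side="right") - 1, 0, n_bins - 1)
        # drop empty bins, keep density ordering
        occupied = np.unique(idx)
        remap = -np.ones(n_bins, dtype=int)
        remap[occupied] = np.arange(occupied.size)
        reps = np.array([rho[idx == j].mean() for j in occupied])
        idx = remap[idx]

    bins = [
        MaterialBin(
            bin_id=i,
            representative_ash_density=float(r),
            E=young_modulus(float(r)),
            sigma_Y=yield_stress(float(r)),
            nu=nu,
        )
        for i, r in enumerate(reps)
    ]
    return MaterialTable(bins=bins, element_bin=np.asarray(idx, dtype=int),
                         n_bins=int(n_bins), element_ash_density=rho)


def elasticity_matrix(E: float, nu: float = DEFAULT_NU) -> np.ndarray:
    """Isotropic 6x6 stress-strain matrix, Voigt order (xx, yy, zz, xy, yz, zx).

    Engineering shear strains are used, so the shear diagonal carries
    (1/2 - nu) under the common factor E / ((1 + nu)(1 - 2 nu)).
    """
    if E <= 0:
        raise ValueError("E must be positive")
    if not 0.0 < nu < 0.5:
        raise ValueError("nu must lie in (0, 0.5); nu >= 0.5 is singular")
    f = E / ((1.0 + nu) * (1.0 - 2.0 * nu))
    d = np.zeros((6, 6))
    d[:3, :3] = nu
    np.fill_diagonal(d[:3, :3], 1.0 - nu)
    d[3, 3] = d[4, 4] = d[5, 5] = 0.5 - nu
    return f * d
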