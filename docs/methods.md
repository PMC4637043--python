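# Methods

This note records the modelling decisions behind `femrisk`: what each
stage computes, the defaults and why, what the synthetic phantom does and
does not emulate, and the numerical conventions.

## Material model

CT attenuation is converted element-wise to ash density by the linear
calibration ρ_ash = 0.04162 + 0.000854·HU (g/cm³), then to Young's
modulus E = 10500·ρ_ash^2.29 MPa and yield stress σ_Y = 116·ρ_ash^2.03
MPa, with a constant Poisson ratio ν = 0.4. Density is clamped below at
0.01 g/cm³: the calibration turns nonpositive near −49 HU (air/marrow),
and stiffness must remain positive; bone segmented at ≥100 HU never
reaches the clamp.

Elements are grouped into discrete material bins (default 50, the count
beyond which FE displacements no longer change appreciably). Binning is
equal-width **on ash density**, not HU — density is the physical variable
entering the power laws. Each nonempty bin's representative density is
the **mean** of its members (not the interval midpoint), which preserves
the mean stiffness of the population; when the requested bin count
reaches the number of distinct densities, every distinct value gets its
own bin, so binned and unbinned stiffness coincide exactly. Element HU is
used directly (no nodal interpolation), consistent with per-element bins.

The 6×6 isotropic elasticity matrix uses Voigt order
(xx, yy, zz, xy, yz, zx) with engineering shear strains, hence (½ − ν) on
the shear diagonal under the factor E/((1+ν)(1−2ν)).

## Finite elements and load cases

Constant-strain 4-node tetrahedra in the mm–N–MPa system; element
stiffness k_e = V_e·BᵀDB; assembly into a sparse symmetric system solved
by direct factorisation. Fully fixed nodes and oblique single-direction
constraints (the fall case holds the head surface only along the load
direction) are imposed with Lagrange multipliers; the linear-solver
contract is a relative residual ≤ 1e-8, checked after every solve, with a
descriptive error (counting near-zero modes) when constraints leave
rigid-body motion. Per element the solver recovers strain, stress,
strain-energy density ½σᵀε, von Mises stress from the stress deviator,
and von Mises strain from principal strains as
(1/(1+ν'))·√(½Σ(ε_i−ε_j)²) with ν' = 0.4 (the material value), the common
equivalent-strain convention in commercial FE output.

Node-set selection for boundary conditions is geometric: head = surface
nodes within 1.05 × head radius of the head centre; trochanter = surface
nodes within 12 mm of the greater-trochanter landmark; distal = nodes
within 5 mm of the distal end plane (all configurable). Forces are split
equally over the selected nodes; the difference from consistent surface
tractions vanishes with refinement, and restricting load/constraint sets
to contact-facing hemispheres changed the risk indices by under 5%, so
the simpler capture-ball rule is kept. The fall impact direction is
perpendicular to the shaft axis within the neck–shaft plane, pointing
medially; the alternative frontal-plane convention is configurable. For
the analytic validation fixtures, `face_force_distribution` provides
area-weighted (consistent) nodal forces so the closed-form uniaxial state
is reproduced to machine precision.

## Anatomy

The head sphere is an algebraic least-squares fit, iterated with a
band-pass on radial residuals to reject neck-junction points. Axis
estimation exploits a property of near-cylindrical regions: the area
centroid of *any* plane cut of a circular cylinder lies on its axis. The
shaft axis is a principal-direction fit of a distal surface band, refined
by a line fit through slice centroids; the neck axis is a chain of slice
centroids between the head surface and the trochanteric junction
(detected as an area jump above 1.12 × the running baseline, and capped
at 80% of the arc length to the shaft axis), anchored at the fitted head
centre — the anchor gives the direction a ~25 mm lever arm, which is what
makes the estimate robust on coarse, faceted meshes where a plain
principal-axis fit of the short, wide neck band picks a radial direction.
On default phantoms the recovered neck-shaft angle is within ~0.6° of the
constructed value across 110–140°.

Critical sections: planes normal to the neck axis are sampled at 1 mm
steps (the common CT slice thickness) over configurable fractions of the
head-centre-to-shaft-axis arc length — neck segment 50–80%, trochanteric
segment 80–115%; the paper-free choice of bounds is exposed rather than
hard-coded. The smallest-area and largest-area stations give the neck and
intertrochanteric sections; area ties (relative 1e-9) break toward the
head so constant-radius geometry is deterministic. The subtrochanteric
plane is fixed by definition: 50 mm distal to the lesser trochanter along
the shaft axis. Cross-section areas are exact polygon areas of the
plane/tet intersection.

## Section energy and the risk index

Section integrals are triangle-Gauss quadrature sums ΣΣ W_i·|J|·û over a
2D triangulation of the section; both U (load-induced, û = ½σᵀε of the
containing tet) and U_Y (û_Y = σ_Y²/(2E) of the containing element's bin)
integrate a volumetric energy density over an area and are therefore
energies **per unit thickness** (N·mm/mm). Their ratio η = U/U_Y is
dimensionless, so the thickness factor cancels; the units are documented
rather than "corrected".

Quadrature rules are the standard symmetric ones: 3 interior points
(barycentric permutations of (2/3, 1/6, 1/6), equal weights; degree-2
exact) and 7 points (centroid + two orbits at (6±√15)/21; degree-5
exact). The 3-point rule is the default; the 7-point rule is kept for
verification.

Two triangulation modes exist. `conforming` fan-triangulates the per-tet
intersection polygons: triangles never straddle elements, so for the
piecewise-constant density fields of linear tets the quadrature equals
the brute-force triangle sum exactly and both rules agree to round-off.
`independent` (the default, mirroring a separately meshed section
boundary) merges the boundary-face cut segments into outline loops —
keyed by mesh edge, so loops close without floating-point vertex matching
— ear-clips them and refines by 4:1 subdivision to the 5 mm converged
edge length; integration points are then located in the tet mesh
individually (k-d tree over centroids + barycentric test, −1e-9
tolerance, lowest-index nearest-tet fallback on shared faces), which is
what makes the 3- and 7-point rules differ slightly at element
boundaries. Ear clipping requires simply connected loops; a faceted
surface can carry small handles near the trochanteric junction, which the
code detects as a mismatch between the triangulated and the exact slice
area (relative 1e-9) and resolves by falling back to the conforming
decomposition for that plane. In every mode the summed triangle area
equals the exact section area.

## The synthetic phantom

The phantom emulates what the downstream stages need from a segmented
QCT femur, nothing more: a shaft ∪ angled-neck ∪ spherical-head solid
with a high-HU cortical shell over a low-HU cancellous interior, named
landmarks, and a constructed (hence exactly known) neck-shaft angle.
Defaults describe an adult femur: shaft 140 × r14 mm, neck 45 × r15 mm,
head r23 mm, angle 130°, cortical 1500 HU, cancellous 150 HU, Gaussian HU
noise (sd 20, clamped at 1 HU), 8 mm target edge (the converged FE edge
length). The cortical shell is classified per element by centroid depth
and is **region-dependent** — 6 mm diaphyseal cortex, 2 mm trochanteric
band above the lesser-trochanter level, 1.5 mm neck, 1 mm head —
reflecting the real distribution that makes the neck the fragile site;
with a uniform shell the stance case would place the highest index at the
subtrochanteric section, which is anatomically wrong. An optional
Gaussian "waist" can be machined into the neck radius to give the
smallest-neck search a known ground-truth location.

Meshing tetrahedralises a body-centred-cubic point lattice (its Delaunay
is the disphenoid honeycomb: congruent well-shaped tets, maximum edge
equal to the lattice spacing, no slivers) and keeps tets whose centroid
lies inside the implicit solid; the largest connected component is
retained and orientations fixed positive. This guarantees the max-edge
bound and bit-exact determinism. The bar fixture is a structured 6-tet
cube split (volume exact); the cylinder extrudes a ring-pattern disc mesh
into prisms split with min-index-consistent diagonals (volume within
faceting error, ≤2% at default edges).

What the phantom does **not** emulate: real cortical-thickness gradients,
trabecular anisotropy, the greater/lesser trochanter prominences (they
are stored landmarks, not surface features), anteversion, curvature of
the shaft, or calibration error in the HU field. Passing tests therefore
demonstrate the correctness of the computational chain on known geometry,
not clinical validity on real femora; absolute index values on the
phantom are smaller than published clinical averages (e.g. the fall-case
neck index is ~0.24 at 700 N / 170 cm versus clinical averages around
0.65), while the qualitative structure — fall ≫ stance at the neck and
intertrochanteric sections, negligible subtrochanteric risk in a fall,
neck > intertrochanteric > subtrochanteric ranking — is reproduced. As in
the published clinical tables, the subtrochanteric index is *higher* in
stance than in a fall: stance bending loads the shaft, whereas the fall
load path bypasses it.

## Numerical conventions and problem sizes

* Plane slicing nudges nodes lying exactly on a plane to one side
  (1e-12 of the coordinate scale) for a consistent cut topology.
* Tet orientation is normalised to positive signed volume at
  construction; solvers and slicers assume it.
* All randomness flows through `numpy.random.default_rng` seeded from
  the spec/config seed; identical inputs give bit-identical meshes,
  solutions and indices.
* Default problem sizes keep a full pipeline run (phantom, two solves,
  three sections) around two seconds: ~3.5 k elements at the 8 mm
  converged edge. The convergence utilities sweep mesh edge, bin count,
  section edge and rule order around these defaults.
* The mesh-edge convergence study is meaningful only when the material
  field does not change with resolution; on the default phantom the
  centroid-classified shell re-discretises with the mesh, so the study
  (and its test) uses a uniform-material phantom. Likewise the bin-count
  study uses a broad HU distribution, since the default near-bimodal
  field is represented losslessly by almost any bin count.

## Known limitations

* Linear kinematics and materials only: no contact, no post-yield
  redistribution, no dynamic impact — the fall is a static equivalent
  load.
* Equal nodal force splitting over capture regions is mesh-dependent at
  coarse resolution.
* The strain-energy index is an energy ratio per unit thickness on a
  plane; it flags sections, not failure surfaces or crack paths.
* Imported meshes must provide the four landmarks (head centre, greater
  and lesser trochanter, distal end centre) and, for load building, a
  head radius in metadata or fitted axes.
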