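# Methods

This note documents the model implemented in `sijfem`: its assumptions,
the parameters that matter, the numerics, and what the synthetic set-up
can and cannot say about real pelves.

## Synthetic geometry

The pelvis surrogate is three structured tetrahedral bodies (sacrum, two
ilia) in a mm/N/MPa unit system with x medio-lateral (left at x > 0),
y antero-posterior (anterior at y > 0) and z cranial-caudal (cranial at
z > 0).  The auricular (SIJ) surfaces are conformal offset surfaces: both
sides share a shape function

    s(y, z) = tan(inclination) · (z − z_c) + curvature · bump(y, z)

added to the sacrum half-width, with the ilium face offset laterally by
the joint gap.  The inclination makes cranial ilium motion close the
joint (the load-bearing wedge of the real SIJ); the cosine bump provides
the interlocking curvature of the auricular surface.  Anterior of the
auricular region each ilium tapers smoothly toward the midline and ends
in a parallel section forming the pubic symphysis faces.

Variant defaults (chosen once as a plausible morphological contrast, and
exposed as parameters): `female_like` curvature 3 mm / inclination 15°,
`male_like` curvature 5 mm / inclination 20° (the deeper, more interlocked
joint).  Joint gap default 2.9 mm — strictly inside the 3 mm SIJ cartilage
thickness so contact engages under load; pubic gap 3.6 mm against its
4 mm clearance.  Overall scale, curvature, inclination and gap are user
parameters; the seed drives a small (0.15 mm) interior-node jitter applied
mirror-symmetrically.

The whole model is exactly mirror-symmetric about x = 0 by construction:
the right ilium and the right sacrum half are node-for-node reflections of
the left, and landmarks are snapped on the left and mirrored.  Refinement
levels `coarse`/`medium`/`fine` hold ≈2000 / 4900 / 11500 elements — a
desk-scale version of a three-grid convergence design (real pelvis studies
use 10–100× more elements); the division table is overridable for
paper-scale meshes.

The density generator assigns a cortical shell (elements with ≥3 exterior
nodes, ρ ≈ 1.85 g/cm³) and a trabecular core (ρ ≈ 0.90 g/cm³) with seeded
Gaussian noise, clipped so the mapped moduli stay inside the 4315–22608
MPa band of density-mapped pelvic bone.  Real CT-derived fields have
continuous gradients, anisotropy and site-specific variation that this
two-plateau surrogate does not; tests passing on it show the *machinery*
(mapping, binning, assembly) is correct, not that any particular pelvis is
represented.

## Materials

Density → modulus uses E[GPa] = 6.950 ρ^1.49, converted to MPa internally.
Moduli are discretized into `n_classes` = 40 equal-width bins over the
observed range, each element taking its bin midpoint (binning error ≤ half
a bin width by construction).  Equal-width binning in E (rather than ρ)
was chosen because the target band is stated in modulus units.  Poisson's
ratio is a single global ν = 0.3 (configurable); the mapping source gives
no value.  HU → density calibration (two anchors, default 0 HU → 1.0 and
1600 HU → 2.0 g/cm³, clamped below) only matters for users supplying
CT-like intensity data.

## Ligaments and muscles

Each ligament group is a set of parallel tension-only fibers sharing the
group stiffness equally.  Roster (N/mm): ASL 700, ISL 2800, LPSL 1000,
PSL 400, SS 1400, ST 1500, PS 1000 as 2×500, gluteus maximus 344, gluteus
medius 779.  ISL/ASL/PSL get 3 fibers (they are broad sheets), the rest 1;
the symphysis has its natural 2.  Pre-tension default is 118 N per group,
split across fibers, imposed via the reference length
L_ref = L_inst − F_pre/k.  Muscles default to zero pre-tension: they are
passive stabilizers here, and a tendon pre-load is a separate modelling
question (both are configurable).  The gluteal far ends are fixed spatial
points — the single-point femoral attachment reduction — so muscle forces
react against ground.

Fiber kinematics are large-displacement (direction updates with
deformation) even though strains stay small, because joint motion is the
output of interest; a `geometric_nonlinearity=False` switch linearizes
them for verification.  A fiber exactly at its reference length
contributes material stiffness but no force, which keeps the tangent
well-conditioned at the slack/taut boundary.

In the stiffness sweep, the factor scales k with L_ref held at its
baseline value: reference length and stiffness are treated as independent
inputs, so the carried pre-tension scales with k.  (The alternative —
holding F_pre fixed and recomputing L_ref — mixes the two inputs.)

## Contact

Normal behaviour is a pressure-overclosure law anchored at two points:
p(c0) = 0 with c0 the cartilage thickness (3 mm SIJ, 4 mm symphysis) and
p(0) = p0 with p0 the cartilage modulus (54 MPa SIJ, 5 MPa symphysis).
The exponential form

    p(g) = p0 · (e^{(c0−g)/c0} − 1)/(e − 1),  g < c0

is anchor-exact, smooth and monotone; a linear law sharing both anchors is
available for the contact-type perturbation.  Friction is penalty-
regularized Coulomb (μ = 0.4, stick stiffness 100 MPa/mm of slip).

Discretization is node-to-surface: follower nodes (ilium side for the
SIJs) project onto the target triangulation; the gap is the signed
distance along the vertex-averaged, barycentrically interpolated outward
normal.  The smoothed normal keeps forces continuous when a projection
crosses facet boundaries — with faceted normals the conformal surfaces sit
exactly on the discontinuities and equilibrium chatters.  Tie-breaks on
equidistant triangles go to the lowest triangle index.  Friction slip is
measured against the *reference-configuration* projection (the material
point each node initially faces), so the friction force is history-free
and continuous under projection migration; this elastic-slip treatment is
adequate for monotonic quasi-static loading but would not capture cyclic
stick-slip hysteresis.  The pubic pair is assembled two-pass (both sides
act as follower at half tributary area), which keeps the discrete operator
mirror-symmetric.

## Solver

Quasi-static equilibrium is solved in two phases: (0) pre-tension
equilibration at zero external load, then (1) the external load in 5 equal
increments.  Each step is Newton iteration with an exact tangent
(including the sliding-friction tangent, which has zero stiffness along
the slip direction plus a pressure-coupling term), a direct sparse LU
factorization, and a backtracking line search.  Contact projections are
frozen during each Newton solve and refreshed in an outer loop until the
refreshed residual also meets tolerance — standard practice that restores
quadratic convergence.  Convergence: ‖R‖ < tol · (‖F_ext‖ + 1 N) with
tol = 1e-6 by default; the attainable floor on the coarse model is ≈1e-9
(double-precision accumulation over ~kN internal forces).  The load
incrementation scheme and tolerances are this package's own choices.

Hip loads enter through distributing couplings: the force at the hip
center is spread over the nearby ilium surface nodes as a statically
equivalent system (equal resultant, zero net moment about the reference
point).

## Outputs

Surface stress summaries are computed over the tetrahedra owning a patch's
triangles: mean, population sd, median, and the 99th percentile with
linear interpolation between order statistics; area weighting is off by
default.  Joint kinematics come from least-squares (Kabsch) rigid fits of
the two patch displacement fields; the relative transform is ilium-fit
composed with the inverse sacrum-fit, translation is evaluated at the
joint-gap centroid (origin-independent) and rotation is the total angle.
This surface-fit motion metric is this package's convention.

Sensitivity s is the least-squares slope of the relative output change
against the input-factor change over the sweep (baseline factor 1.0); on
symmetric three-point sweeps this equals the central difference.  Sweeps
default to three points (endpoints + baseline): reference length
0.998–1.0, stiffness 0.6–1.4, load 0.6–1.4.  The rigid-fit motion metrics
are linear in the displacement field only to first order, so the exact
linear-limit identity (s = 1 for load intensity in a fully linear
configuration) is verified at small load amplitude where the metric
nonlinearity is negligible.

Perturbation studies: gluteal attachment shift (−10 mm medial / +20 mm
lateral, mirrored across sides), linear vs exponential SIJ contact,
friction μ ∈ {0.2, 0.4, 0.6}, and overclosure (cartilage-thickness
surrogate) scaled ±20 % — the overclosure range is this package's choice.
The convergence study solves the symmetric-xyz scenario (the highest-
response case) on the three grids and reports differences relative to the
finest plus solve-time ratios.

## Degenerate inputs and validation

Non-positive scale or joint gap, unknown variants/refinements, missing
landmarks, empty lumbosacral patches, inverted elements, identical HU
anchors, unphysical shortening (F_pre/k ≥ L_inst), collinear patch fits
and unknown scenario names are all rejected with named errors before any
solving.  Mesh files round-trip nodes, connectivity, patches and the
landmark sidecar exactly in both supported dialects (ASCII VTU, Gmsh MSH
4.1).

## Known limitations

* The geometry is a block-level surrogate; absolute stresses and motions
  are not comparable to any specific pelvis, only structure (signs,
  relative magnitudes, symmetry) is meaningful.
* Cartilage lives entirely in the contact law; there is no meshed
  cartilage volume.
* Bone is linear-elastic and isotropic; no cortical/trabecular
  constitutive split beyond the density contrast.
* Friction has no slip history (no cyclic hysteresis).
* The synthetic gait curve reproduces only the printed peak magnitudes
  and phase structure of instrumented-implant data, not measured
  waveforms; real per-phase force vectors live in external databases and
  are not packaged.
* Muscles are passive springs; no active force estimation.
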