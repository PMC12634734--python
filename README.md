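# sijfem — sacroiliac-joint finite-element toolkit

`sijfem` is a self-contained simulator of sacroiliac-joint (SIJ)
biomechanics for researchers studying how ligament laxity — stiffness and
pre-tension — shapes joint loading and mobility.  The sacroiliac joint
transmits the load between spine and lower limbs; it is stabilized by a
network of strong ligaments (interosseous, anterior/posterior/long
posterior sacroiliac, sacrospinous, sacrotuberous, pubic symphysis) and the
gluteal muscles.  Cadaver work reports a substantial in-situ pre-load in
the sacrotuberous ligament (~118 N), yet most finite-element models of the
SIJ ignore ligament pre-tension altogether.  This package exists to
quantify how much that assumption matters, relative to ligament stiffness
and to the patient's body weight.

## The model

* **Geometry.** A parametric, seeded, exactly mirror-symmetric synthetic
  pelvis surrogate (sacrum and two ilia as tetrahedral bodies) with
  labelled auricular surfaces, pubic symphysis faces, a lumbosacral
  fixation surface, ligament/muscle attachment landmarks and per-side hip
  centers.  Two morphology variants (`female_like` / `male_like`) differ
  in auricular curvature and inclination.  This is an idealized surrogate,
  not an anatomical reconstruction: the quantities under study are
  *sensitivities*, not absolute anatomy.
* **Bone.** Isotropic inhomogeneous elasticity mapped from apparent
  density via the power law `E = 6.950 ρ^1.49` (ρ in g/cm³, E in GPa),
  discretized into 40 equal-width material classes; linear 4-node
  tetrahedra.
* **Ligaments and muscles.** Tension-only springs with literature
  stiffnesses (e.g. ISL 2800 N/mm, ST 1500 N/mm, PS 2×500 N/mm, gluteus
  maximus 344 N/mm).  Pre-tension `F_pre` is imposed by shortening the
  stress-free reference length: `L_ref = L_inst − F_pre/k`, so a spring
  held at its installed length carries exactly `F_pre` (118 N per ligament
  group by default — for the sacrotuberous ligament this is a shortening
  to ~99.92 % of the installed length).
* **Contact.** Node-to-surface contact at both SIJs and the pubic
  symphysis with an exponential pressure-overclosure law anchored at the
  cartilage thickness (zero pressure at clearance `c0` = 3 mm SIJ / 4 mm
  symphysis) and the cartilage modulus (`p0` = 54 / 5 MPa at zero
  clearance), plus penalty-regularized Coulomb friction (μ = 0.4).
* **Loads.** Eight generic scenarios built from the extreme gait load
  components (Fx = 600 N, Fy = 1200 N, Fz = 2400 N; per axis or combined,
  unilateral or bilateral), and five quasi-static gait phases (IHS, CTO,
  swing, CHS, ITO) sampled from a synthetic gait curve with exactly those
  peak magnitudes.  The sacrum is fixed at the lumbosacral surface; hip
  forces enter through distributing couplings at the hip centers.
* **Outputs.** Surface von Mises summaries (mean ± sd, median, 99th
  percentile), relative SIJ translation/rotation from least-squares rigid
  fits of the articular-surface displacement fields, and normalized
  one-at-a-time sensitivities `s = Δoutput/Δinput` for ligament reference
  length (0.998–1), ligament stiffness (0.6–1.4) and load intensity
  (0.6–1.4), plus perturbation studies (attachment shift, linear vs
  exponential contact, friction 0.2–0.6, overclosure) and a three-level
  mesh-convergence study.

## Worked example

```python
from sijfem import build_model, solve_quasistatic, generic_scenarios
from sijfem.sensitivity import model_outputs, sweep_parameter, sensitivities_all_outputs

model = build_model(variant="female_like", seed=1)          # coarse mesh, ~2000 tets
case = {c.name: c for c in generic_scenarios()}["symmetric_xyz"]
sol = solve_quasistatic(model, case.side_forces())
print(model_outputs(sol, model.mesh))
# {'mean_stress': 3.513, 'mean_translation': 0.387, 'mean_rotation': 0.586}

table = sweep_parameter("ligament_reference_length", [0.998, 0.999, 1.0],
                        model_kwargs={"variant": "female_like", "seed": 1})
print(sensitivities_all_outputs(table, "ligament_reference_length"))
# {'mean_stress': 8.9, 'mean_translation': 76.9, 'mean_rotation': 72.8}
```

The first block solves the combined bilateral load case: the articular
surfaces carry a mean von Mises stress of ≈3.5 MPa and the ilium moves
≈0.39 mm / 0.59° relative to the sacrum — sub-millimetre motion, as
expected for an intact SIJ.  The sweep then shows the headline effect:
relaxing the ligament reference length by just 0.2 % (i.e. removing the
pre-tension) changes the relative translation with a normalized
sensitivity of ≈77 — versus ≈1.6 for body weight and ≈−1.6 for ligament
stiffness in the same setup.  Joint mobility is governed by ligament
pre-tension far more than by load intensity.

The same studies are scriptable from the shell:

```bash
sijfem solve --variant female_like --scenario symmetric_xyz --seed 1
sijfem sweep --input ligament_stiffness --from 0.6 --to 1.4 --points 3
sijfem perturb --which friction_0.2_to_0.6
sijfem run-study --seed 1 --out results/study
```

`run-study` solves both morphology variants under all 13 load cases and
writes wide CSV tables (`stress_mean.csv`, `kinematics_translation.csv`,
`kinematics_rotation.csv`, `sensitivity.csv`) with a provenance record.

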