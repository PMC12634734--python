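"""Model assembly: from morphology parameters to a ready-to-solve FEModel.

This is the single place where the study's default physical parameters are
wired together: the Table-1 ligament roster with 118 N group pre-tension,
the SIJ contact law (3 mm cartilage, 54 MPa) and pubic symphysis law
(4 mm, 5 MPa) with friction 0.4, the 40-class density-mapped bone moduli,
the lumbosacral fixation and the per-side hip couplings.

The keyword knobs cover the sensitivity and perturbation studies:
multiplicative reference-length and stiffness factors, contact law type,
friction, overclosure scaling and gluteal attachment shifts.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .contact import ContactLaw, ContactPairDef, PUBIC_LAW, SIJ_LAW
from .fe import FEModel, SolverSettings
from .geometry import MorphologyParams, build_pelvis_mesh, generate_density_field
from .ligaments import default_ligament_specs, install_all
from .loads import apply_boundary_conditions
from .materials import material_from_density
from .mesh import TetMesh


def contact_pairs(
    law_type: str = "exponential",
    friction: float = 0.4,
    overclosure_scale: float = 1.0,
    stick_stiffness: float = 100.0,
    pubic_contact: bool = True,
) -> list[ContactPairDef]:
    """The three contact pairs: left/right SIJ and the pubic symphysis.

    ``overclosure_scale`` scales the zero-pressure clearance c0 (the
    cartilage-thickness surrogate); ``law_type`` switches the SIJ pairs
    between the exponential and linear pressure-overclosure laws.
    """
    sij = ContactLaw(
        c0=SIJ_LAW.c0 * overclosure_scale, p0=SIJ_LAW.p0, mu=friction,
        law=law_type, stick_stiffness=stick_stiffness,
    )
    pub = ContactLaw(
        c0=PUBIC_LAW.c0 * overclosure_scale, p0=PUBIC_LAW.p0, mu=friction,
        law="exponential", stick_stiffness=stick_stiffness,
    )
    pairs = [
        ContactPairDef("sij_ilium_left", "sij_sacrum_left", sij),
        ContactPairDef("sij_ilium_right", "sij_sacrum_right", sij),
    ]
    if pubic_contact:
        # two-pass pairing keeps the symphysis discretization
        # mirror-symmetric (each side acts as follower at half area)
        pairs.append(ContactPairDef("pubic_left", "pubic_right", pub, area_scale=0.5))
        pairs.append(ContactPairDef("pubic_right", "pubic_left", pub, area_scale=0.5))
    return pairs


def build_model(
    variant: str = "female_like",
    refinement: str = "coarse",
    seed: int = 0,
    *,
    params: MorphologyParams | None = None,
    mesh: TetMesh | None = None,
    pretension: float = 118.0,
    muscle_pretension: float = 0.0,
    pretension_enabled: bool = True,
    reference_length_scale: float = 1.0,
    stiffness_scale: float = 1.0,
    attachment_shift: float = 0.0,
    law_type: str = "exponential",
    friction: float = 0.4,
    overclosure_scale: float = 1.0,
    contact_enabled: bool = True,
    pubic_contact: bool = True,
    n_classes: int = 40,
    poisson: float = 0.3,
    density_seed: int | None = None,
    density_noise: float = 1.0,
    settings: SolverSettings | None = None,
) -> FEModel:
    """Assemble the full pelvis model for one morphology variant.

    ``reference_length_scale`` multiplies every fiber's stress-free
    reference length (values < 1 increase pre-tension); ``stiffness_scale``
    multiplies every fiber stiffness with the reference length held, so the
    carried pre-tension scales with the stiffness.  ``attachment_shift``
    moves the gluteal ground points medio-laterally (negative = medial) in
    mm, mirrored across sides.
    """
    if mesh is None:
        if params is None:
            params = MorphologyParams(variant=variant, seed=seed)
        mesh = build_pelvis_mesh(params, refinement)
    if attachment_shift != 0.0:
        landmarks = dict(mesh.landmarks)
        for side, sign in (("left", +1.0), ("right", -1.0)):
            name = f"gluteal_ground_{side}"
            p = landmarks[name].copy()
            p[0] += sign * attachment_shift  # lateral positive
            landmarks[name] = p
        mesh = replace(mesh, landmarks=landmarks)

    dens = generate_density_field(
        mesh, seed=seed if density_seed is None else density_seed,
        noise=density_noise,
    )
    material = material_from_density(dens.rho, n_classes=n_classes, poisson=poisson)

    specs = default_ligament_specs(
        pretension=pretension,
        muscle_pretension=muscle_pretension,
        pretension_enabled=pretension_enabled,
    )
    springs = install_all(specs, mesh)
    if stiffness_scale != 1.0:
        springs.stiffness = springs.stiffness * stiffness_scale
    if reference_length_scale != 1.0:
        springs.length_reference = springs.length_reference * reference_length_scale

    st = settings or SolverSettings()
    st.contact_enabled = st.contact_enabled and contact_enabled
    model = FEModel(
        mesh=mesh,
        material=material,
        springs=springs,
        contact_pairs=contact_pairs(
            law_type=law_type, friction=friction,
            overclosure_scale=overclosure_scale, pubic_contact=pubic_contact,
        ),
        settings=st,
    )
    return apply_boundary_conditions(model)
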