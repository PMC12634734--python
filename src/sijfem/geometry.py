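"""Parametric synthetic pelvis geometry.

The generator builds an idealized articulated pelvis surrogate — a sacrum
block flanked by two ilium blocks — rather than an anatomical
reconstruction.  What matters for the mechanics under study is preserved:

* paired auricular (SIJ) surfaces separated by a small cartilage-scale gap,
  shaped by a curvature bump and a cranio-caudal inclination so that
  vertical load wedges the joint into compression;
* an anterior pubic bridge where the two ilia approach the midline and meet
  across a second contact gap (the pubic symphysis);
* a lumbosacral surface on top of the sacrum for the fixation boundary
  condition;
* ligament/muscle attachment landmarks and per-side hip centers.

The two morphology variants (``female_like`` / ``male_like``) differ only in
the auricular curvature and inclination parameters.  The whole model is
exactly mirror-symmetric about the mid-sagittal plane x = 0: the right half
is generated by reflecting the left half node-for-node.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mesh import (
    BONE_NAMES,
    MeshError,
    TetMesh,
    fix_orientation,
    merge_meshes,
    orient_patch_outward,
    tet_faces,
    boundary_face_owners,
)

# ---------------------------------------------------------------------------
# template dimensions (mm, scale = 1)

SACRUM_HALF_WIDTH = 22.0
SACRUM_Y = (-50.0, -14.0)          # antero-posterior extent of the sacrum
Z_RANGE = (-35.0, 25.0)            # shared cranio-caudal extent
ILIUM_Y = (-50.0, 45.0)            # the ilium runs forward to the pubis
Y_JOINT_END = -14.0                # anterior end of the auricular region
Y_PUBIC_START = 25.0               # start of the parallel pubic section
THICKNESS_POSTERIOR = 14.0
THICKNESS_ANTERIOR = 8.0
PUBIC_GAP = 3.6                    # total midline gap at the symphysis (mm)

_REFINEMENT = {
    # (sacrum half u, sacrum v) , ilium u, (ilium v per segment), shared nz
    "coarse": dict(sac_u=2, sac_v=4, il_u=2, il_v=(4, 4, 2), nz=6),
    "medium": dict(sac_u=3, sac_v=5, il_u=3, il_v=(5, 5, 2), nz=8),
    "fine": dict(sac_u=4, sac_v=7, il_u=4, il_v=(7, 7, 3), nz=10),
}

_VARIANT_DEFAULTS = {
    # curvature amplitude (mm at scale 1), inclination (deg); the male-like
    # joint gets the deeper, more inclined (more interlocked) surface
    "female_like": (3.0, 15.0),
    "male_like": (5.0, 20.0),
}


@dataclass(frozen=True)
class MorphologyParams:
    """Parameters of the synthetic pelvis surrogate.

    ``curvature`` (mm) and ``inclination`` (deg) shape the auricular
    surfaces; when left as ``None`` they take variant-specific defaults.
    ``joint_gap`` is the initial SIJ clearance in physical mm (not scaled),
    chosen below the SIJ cartilage thickness so contact engages under load.
    ``jitter`` perturbs interior nodes (mirror-symmetrically) by up to the
    given amplitude in mm, seeded by ``seed``.
    """

    variant: str = "female_like"
    scale: float = 1.0
    curvature: float | None = None
    inclination: float | None = None
    joint_gap: float = 2.9
    jitter: float = 0.15
    seed: int = 0

    def resolved(self) -> "MorphologyParams":
        if self.variant not in _VARIANT_DEFAULTS:
            raise MeshError(
                f"unknown variant {self.variant!r}; expected one of "
                f"{sorted(_VARIANT_DEFAULTS)}"
            )
        curv, incl = _VARIANT_DEFAULTS[self.variant]
        out = self
        if out.curvature is None:
            out = replace(out, curvature=curv)
        if out.inclination is None:
            out = replace(out, inclination=incl)
        return out


# ---------------------------------------------------------------------------
# structured block helpers


def _segmented_axis(breaks: list[float], divisions: list[int]) -> np.ndarray:
    """1-D grid through the given breakpoints with per-segment divisions."""
    pts = [np.array([breaks[0]])]
    for a, b, n in zip(breaks[:-1], breaks[1:], divisions):
        pts.append(np.linspace(a, b, n + 1)[1:])
    return np.concatenate(pts)


_HEX_TETS = np.array(
    [
        [0, 1, 2, 6],
        [0, 2, 3, 6],
        [0, 3, 7, 6],
        [0, 7, 4, 6],
        [0, 4, 5, 6],
        [0, 5, 1, 6],
    ]
)


class _Block:
    """A structured hex block split into tetrahedra."""

    def __init__(self, u: np.ndarray, v: np.ndarray, w: np.ndarray):
        self.shape = (len(u), len(v), len(w))
        U, V, W = np.meshgrid(u, v, w, indexing="ij")
        self.param = np.stack([U.ravel(), V.ravel(), W.ravel()], axis=1)
        self.nodes = self.param.copy()
        nu, nv, nw = self.shape
        i, j, k = np.meshgrid(
            np.arange(nu - 1), np.arange(nv - 1), np.arange(nw - 1), indexing="ij"
        )
        i, j, k = i.ravel(), j.ravel(), k.ravel()
        nid = lambda a, b, c: (a * nv + b) * nw + c
        corners = np.stack(
            [
                nid(i, j, k),
                nid(i + 1, j, k),
                nid(i + 1, j + 1, k),
                nid(i, j + 1, k),
                nid(i, j, k + 1),
                nid(i + 1, j, k + 1),
                nid(i + 1, j + 1, k + 1),
                nid(i, j + 1, k + 1),
            ],
            axis=1,
        )
        self.tets = corners[:, _HEX_TETS].reshape(-1, 4)

    def nid(self, i, j, k):
        nu, nv, nw = self.shape
        return (np.asarray(i) * nv + np.asarray(j)) * nw + np.asarray(k)

    def face_quads(self, axis: int, end: int, vmask=None) -> np.ndarray:
        """Quads of one block face; ``vmask(c1, c2)`` filters by the two
        in-face cell indices."""
        nu, nv, nw = self.shape
        sizes = (nu, nv, nw)
        fixed = 0 if end == 0 else sizes[axis] - 1
        other = [a for a in range(3) if a != axis]
        n1, n2 = sizes[other[0]] - 1, sizes[other[1]] - 1
        c1, c2 = np.meshgrid(np.arange(n1), np.arange(n2), indexing="ij")
        c1, c2 = c1.ravel(), c2.ravel()
        if vmask is not None:
            keep = vmask(c1, c2)
            c1, c2 = c1[keep], c2[keep]

        def corner(d1, d2):
            idx = [None, None, None]
            idx[axis] = np.full_like(c1, fixed)
            idx[other[0]] = c1 + d1
            idx[other[1]] = c2 + d2
            return self.nid(*idx)

        return np.stack(
            [corner(0, 0), corner(1, 0), corner(1, 1), corner(0, 1)], axis=1
        )

    def interior_mask(self) -> np.ndarray:
        nu, nv, nw = self.shape
        p = self.param.reshape(nu, nv, nw, 3)
        m = np.zeros((nu, nv, nw), bool)
        m[1:-1, 1:-1, 1:-1] = True
        return m.ravel()


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _triangulate_quads(quads: np.ndarray, face_set: set) -> np.ndarray:
    """Split boundary quads along the diagonal used by the tetrahedra."""
    tris = []
    for a, b, c, d in quads:
        t1, t2 = (a, b, c), (a, c, d)
        if tuple(sorted(t1)) in face_set and tuple(sorted(t2)) in face_set:
            tris += [t1, t2]
        else:
            tris += [(a, b, d), (b, c, d)]
    return np.array(tris, dtype=int)


def _mirror_x(nodes: np.ndarray, tets: np.ndarray):
    out = nodes * np.array([-1.0, 1.0, 1.0])
    return out, fix_orientation(out, tets)


# ---------------------------------------------------------------------------
# the pelvis builder


def build_pelvis_mesh(
    params: MorphologyParams,
    refinement: str = "coarse",
    divisions: dict | None = None,
) -> TetMesh:
    """Generate the synthetic articulated pelvis.

    Parameters
    ----------
    params
        Morphology parameters; see :class:`MorphologyParams`.
    refinement
        One of ``coarse``, ``medium``, ``fine``.  Element counts grow
        strictly with refinement.
    divisions
        Optional override of the per-level grid divisions (same keys as the
        internal refinement table); allows research-scale meshes.
    """
    params = params.resolved()
    if params.scale <= 0:
        raise MeshError(f"scale must be > 0, got {params.scale}")
    if params.joint_gap <= 0:
        raise MeshError(f"joint_gap must be > 0, got {params.joint_gap}")
    if refinement not in _REFINEMENT:
        raise MeshError(
            f"unknown refinement {refinement!r}; expected one of "
            f"{sorted(_REFINEMENT)}"
        )
    div = dict(_REFINEMENT[refinement])
    if divisions:
        div.update(divisions)

    s = params.scale
    gap = params.joint_gap
    incl = np.tan(np.radians(params.inclination))
    curv = params.curvature * s
    yc = s * 0.5 * (SACRUM_Y[0] + SACRUM_Y[1])
    zc = s * 0.5 * (Z_RANGE[0] + Z_RANGE[1])
    Ly = s * (SACRUM_Y[1] - SACRUM_Y[0])
    Lz = s * (Z_RANGE[1] - Z_RANGE[0])
    y_joint_end = s * Y_JOINT_END
    y_pubic = s * Y_PUBIC_START

    def shape_fn(y, z):
        """Auricular-surface shape offset added to the sacrum half-width."""
        yj = np.minimum(y, y_joint_end)
        bump = np.cos(np.pi * (yj - yc) / Ly) * np.cos(np.pi * (z - zc) / Lz)
        return incl * (z - zc) + curv * bump

    def taper_weight(y):
        """1 in the auricular region, 0 from the pubic section forward."""
        return 1.0 - _smoothstep((y - y_joint_end) / (y_pubic - y_joint_end))

    zgrid = np.linspace(s * Z_RANGE[0], s * Z_RANGE[1], div["nz"] + 1)

    # --- sacrum: half block (x >= 0) mirrored about the mid-sagittal plane
    sac = _Block(
        np.linspace(0.0, 1.0, div["sac_u"] + 1),
        np.linspace(s * SACRUM_Y[0], s * SACRUM_Y[1], div["sac_v"] + 1),
        zgrid,
    )
    u, y, z = sac.param.T
    face = s * SACRUM_HALF_WIDTH + shape_fn(y, z)
    sac.nodes = np.stack([u * face, y, z], axis=1)

    # --- left ilium
    il = _Block(
        np.linspace(0.0, 1.0, div["il_u"] + 1),
        _segmented_axis(
            [s * ILIUM_Y[0], y_joint_end, y_pubic, s * ILIUM_Y[1]], list(div["il_v"])
        ),
        zgrid,
    )
    u, y, z = il.param.T
    w = taper_weight(y)
    x_med = w * (s * SACRUM_HALF_WIDTH + gap + shape_fn(y, z)) + (1.0 - w) * (
        PUBIC_GAP / 2.0
    )
    thick = w * s * THICKNESS_POSTERIOR + (1.0 - w) * s * THICKNESS_ANTERIOR
    il.nodes = np.stack([x_med + u * thick, y, z], axis=1)

    # --- seeded, mirror-symmetric interior jitter
    if params.jitter > 0:
        rng = np.random.default_rng(params.seed)
        for blk in (sac, il):
            mask = blk.interior_mask()
            pert = rng.uniform(-params.jitter, params.jitter, (int(mask.sum()), 3))
            blk.nodes[mask] += pert

    # --- assemble: sacrum (half + mirrored half, sharing the midplane),
    #     left ilium, mirrored right ilium
    sac_nodes, sac_tets, sac_map_m = _mirror_merge_halfblock(sac)
    il_r_nodes, il_r_tets = _mirror_x(il.nodes, il.tets)

    nodes, tets, offs, elem_bone = merge_meshes(
        [
            (sac_nodes, sac_tets),
            (il.nodes, il.tets),
            (il_r_nodes, il_r_tets),
        ]
    )
    # bone ids follow BONE_NAMES: sacrum, ilium_left, ilium_right
    assert BONE_NAMES == ("sacrum", "ilium_left", "ilium_right")
    off_sac, off_l, off_r = offs

    # --- patches
    face_set = {tuple(sorted(f)) for f in tet_faces(tets)}

    def tri(quads, off):
        return _triangulate_quads(quads + off, face_set)

    nv_post = div["il_v"][0]
    nv_taper = div["il_v"][1]
    med_joint = il.face_quads(0, 0, vmask=lambda c1, c2: c1 < nv_post)
    med_pubic = il.face_quads(0, 0, vmask=lambda c1, c2: c1 >= nv_post + nv_taper)
    sac_lat = sac.face_quads(0, 1)
    sac_top_half = sac.face_quads(2, 1)

    patches = {
        "sij_sacrum_left": tri(sac_lat, off_sac),
        "sij_sacrum_right": tri(sac_map_m[sac_lat], off_sac),
        "sij_ilium_left": tri(med_joint, off_l),
        "sij_ilium_right": tri(med_joint, off_r),
        "pubic_left": tri(med_pubic, off_l),
        "pubic_right": tri(med_pubic, off_r),
        "lumbosacral": np.concatenate(
            [tri(sac_top_half, off_sac), tri(sac_map_m[sac_top_half], off_sac)]
        ),
    }
    for name in patches:
        patches[name] = orient_patch_outward(nodes, tets, patches[name])

    landmarks, landmark_nodes = _place_landmarks(
        nodes, elem_bone, tets, s, gap, off_l, off_r
    )

    mesh = TetMesh(
        nodes=nodes,
        tets=tets,
        patches=patches,
        landmarks=landmarks,
        landmark_nodes=landmark_nodes,
        elem_bone=elem_bone,
    )
    mesh.validate()
    return mesh


def _mirror_merge_halfblock(blk: _Block):
    """Mirror a half block built on x >= 0 about x = 0, sharing plane nodes.

    Returns merged (nodes, tets) and an index map applying the mirror to
    node indices of the original half (for remapping patch quads).
    """
    n = blk.nodes.shape[0]
    on_plane = np.isclose(blk.param[:, 0], 0.0)
    mirror_map = np.empty(n, dtype=int)
    extra = []
    nxt = n
    for i in range(n):
        if on_plane[i]:
            mirror_map[i] = i
        else:
            mirror_map[i] = nxt
            extra.append(blk.nodes[i] * np.array([-1.0, 1.0, 1.0]))
            nxt += 1
    nodes = np.concatenate([blk.nodes, np.array(extra).reshape(-1, 3)])
    tets_m = mirror_map[blk.tets]
    tets = np.concatenate([blk.tets, fix_orientation(nodes, tets_m)])
    return nodes, tets, mirror_map


# ---------------------------------------------------------------------------
# landmarks

# (ligament/muscle attachment template positions for the LEFT side;
#  bone is the snap target, or None for fixed spatial points)
_LANDMARK_TEMPLATE = [
    # name, bone, (x, y, z)
    ("ISL_left_sacrum_0", "sacrum", (22.0, -44.0, 10.0)),
    ("ISL_left_sacrum_1", "sacrum", (22.0, -44.0, 0.0)),
    ("ISL_left_sacrum_2", "sacrum", (22.0, -44.0, -10.0)),
    ("ISL_left_ilium_0", "ilium_left", (25.0, -44.0, 10.0)),
    ("ISL_left_ilium_1", "ilium_left", (25.0, -44.0, 0.0)),
    ("ISL_left_ilium_2", "ilium_left", (25.0, -44.0, -10.0)),
    ("ASL_left_sacrum_0", "sacrum", (21.0, -16.0, 8.0)),
    ("ASL_left_sacrum_1", "sacrum", (21.0, -16.0, -2.0)),
    ("ASL_left_sacrum_2", "sacrum", (21.0, -16.0, -12.0)),
    ("ASL_left_ilium_0", "ilium_left", (26.0, -16.0, 8.0)),
    ("ASL_left_ilium_1", "ilium_left", (26.0, -16.0, -2.0)),
    ("ASL_left_ilium_2", "ilium_left", (26.0, -16.0, -12.0)),
    ("PSL_left_sacrum_0", "sacrum", (18.0, -50.0, -8.0)),
    ("PSL_left_sacrum_1", "sacrum", (18.0, -50.0, -18.0)),
    ("PSL_left_sacrum_2", "sacrum", (18.0, -50.0, -28.0)),
    ("PSL_left_ilium_0", "ilium_left", (28.0, -50.0, -8.0)),
    ("PSL_left_ilium_1", "ilium_left", (28.0, -50.0, -18.0)),
    ("PSL_left_ilium_2", "ilium_left", (28.0, -50.0, -28.0)),
    ("LPSL_left_sacrum_0", "sacrum", (16.0, -50.0, -22.0)),
    ("LPSL_left_ilium_0", "ilium_left", (30.0, -46.0, -28.0)),
    ("SS_left_sacrum_0", "sacrum", (14.0, -40.0, -34.0)),
    ("SS_left_ilium_0", "ilium_left", (24.0, -5.0, -34.0)),
    ("ST_left_sacrum_0", "sacrum", (15.0, -50.0, -32.0)),
    ("ST_left_ilium_0", "ilium_left", (32.0, -28.0, -34.0)),
    ("PS_left_0", "ilium_left", (1.8, 36.0, -8.0)),
    ("PS_left_1", "ilium_left", (1.8, 36.0, 4.0)),
    ("gluteus_maximus_left_pelvis_0", "ilium_left", (39.0, -46.0, 12.0)),
    ("gluteus_medius_left_pelvis_0", "ilium_left", (39.0, -6.0, 22.0)),
]

_SPATIAL_TEMPLATE = [
    # the reduced single-point femoral attachment of the gluteal muscles
    ("gluteal_ground_left", (58.0, -25.0, -45.0)),
    # acetabular center: antero-inferior to the SIJ but close to its load axis
    ("hip_center_left", (40.0, -18.0, -22.0)),
]


def _place_landmarks(nodes, elem_bone, tets, scale, gap, off_l, off_r):
    """Snap template landmarks to mesh nodes; mirror for the right side."""
    bone_of_node = np.full(nodes.shape[0], -1, dtype=int)
    for b in range(3):
        bone_of_node[np.unique(tets[elem_bone == b])] = b
    bone_idx = {name: i for i, name in enumerate(BONE_NAMES)}

    landmarks: dict[str, np.ndarray] = {}
    landmark_nodes: dict[str, int] = {}
    mirror = np.array([-1.0, 1.0, 1.0])
    # node lookup for exact mirrored positions
    coord_key = {tuple(np.round(p, 9)): i for i, p in enumerate(nodes)}

    for name, bone, pos in _LANDMARK_TEMPLATE:
        target = np.array(pos) * scale
        cand = np.flatnonzero(bone_of_node == bone_idx[bone])
        j = cand[np.argmin(np.linalg.norm(nodes[cand] - target, axis=1))]
        landmarks[name] = nodes[j].copy()
        landmark_nodes[name] = int(j)
        rname = name.replace("_left", "_right")
        rpos = nodes[j] * mirror
        rj = coord_key.get(tuple(np.round(rpos, 9)))
        if rj is None:  # fall back to nearest-node search on the mirror bone
            rbone = bone_idx["ilium_right"] if bone == "ilium_left" else bone_idx[bone]
            cand = np.flatnonzero(bone_of_node == rbone)
            rj = cand[np.argmin(np.linalg.norm(nodes[cand] - rpos, axis=1))]
        landmarks[rname] = nodes[rj].copy()
        landmark_nodes[rname] = int(rj)

    for name, pos in _SPATIAL_TEMPLATE:
        p = np.array(pos) * scale
        landmarks[name] = p
        landmarks[name.replace("_left", "_right")] = p * mirror

    return landmarks, landmark_nodes


def box_mesh(
    lengths=(1.0, 1.0, 1.0), divisions=(1, 1, 1), origin=(0.0, 0.0, 0.0)
) -> TetMesh:
    """Structured tetrahedral box with face patches x0,x1,y0,y1,z0,z1.

    A small utility for verification problems (patch tests, cantilever
    beams); each hex cell is split into 6 tetrahedra.
    """
    lx, ly, lz = lengths
    nx, ny, nz = divisions
    blk = _Block(
        np.linspace(origin[0], origin[0] + lx, nx + 1),
        np.linspace(origin[1], origin[1] + ly, ny + 1),
        np.linspace(origin[2], origin[2] + lz, nz + 1),
    )
    nodes = blk.nodes
    tets = fix_orientation(nodes, blk.tets)
    face_set = {tuple(sorted(f)) for f in tet_faces(tets)}
    patches = {}
    for name, (axis, end) in {
        "x0": (0, 0), "x1": (0, 1), "y0": (1, 0),
        "y1": (1, 1), "z0": (2, 0), "z1": (2, 1),
    }.items():
        patches[name] = orient_patch_outward(
            nodes, tets, _triangulate_quads(blk.face_quads(axis, end), face_set)
        )
    return TetMesh(
        nodes=nodes, tets=tets, patches=patches,
        elem_bone=np.zeros(len(tets), dtype=int),
    )


# ---------------------------------------------------------------------------
# density field


@dataclass
class DensityField:
    """Per-element apparent density (g/cm^3) with optional synthetic HU."""

    rho: np.ndarray
    hu: np.ndarray | None = None


def generate_density_field(
    mesh: TetMesh,
    seed: int = 0,
    noise: float = 1.0,
    shell_density: float = 1.85,
    core_density: float = 0.90,
) -> DensityField:
    """Synthesize a cortical-shell / trabecular-core density field.

    Elements with at least three nodes on the exterior surface are treated
    as cortical shell.  Seeded Gaussian noise (scaled by ``noise``) is added
    and the result clipped so the mapped moduli stay inside the physiologic
    modulus band of cortical/trabecular bone.
    """
    ext = np.zeros(mesh.n_nodes, dtype=bool)
    bfaces = boundary_face_owners(mesh.tets)
    for f in bfaces:
        ext[list(f)] = True
    n_ext = ext[mesh.tets].sum(axis=1)
    shell = n_ext >= 3

    rng = np.random.default_rng(seed)
    rho = np.where(shell, shell_density, core_density) + noise * np.where(
        shell,
        rng.normal(0.0, 0.10, mesh.n_elements),
        rng.normal(0.0, 0.05, mesh.n_elements),
    )
    rho = np.where(shell, np.clip(rho, 1.55, 2.20), np.clip(rho, 0.74, 1.20))
    hu = (rho - 1.0) * 1600.0  # inverse of the default HU calibration
    return DensityField(rho=rho, hu=hu)
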