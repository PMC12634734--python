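"""Core mesh containers for the pelvis model.

The unit system is mm / N / MPa throughout.  The global frame follows the
loading convention of the study design: x is medio-lateral (midline at x = 0,
the left side at x > 0), y is antero-posterior (anterior at y > 0) and z is
cranial-caudal (cranial at z > 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Surface patches every articulated pelvis mesh must carry.
REQUIRED_PATCHES = (
    "sij_sacrum_left",
    "sij_sacrum_right",
    "sij_ilium_left",
    "sij_ilium_right",
    "pubic_left",
    "pubic_right",
    "lumbosacral",
)

#: Bone body identifiers used in ``elem_bone``.
BONE_NAMES = ("sacrum", "ilium_left", "ilium_right")


class MeshError(ValueError):
    """Raised for invalid or inconsistent mesh data."""


@dataclass
class TetMesh:
    """Tetrahedral mesh of the three pelvis bones with labelled surfaces.

    Attributes
    ----------
    nodes : (n, 3) float array
        Node coordinates in mm.
    tets : (m, 4) int array
        Tetrahedron connectivity, 0-based, positively oriented.
    patches : dict[str, (k, 3) int array]
        Named surface patches as triangle lists.  Triangles are oriented
        with outward normals (counter-clockwise seen from outside the bone).
    landmarks : dict[str, (3,) float array]
        Named landmark points (ligament/muscle attachments, hip centers,
        muscle ground points).
    landmark_nodes : dict[str, int]
        For landmarks that coincide with a mesh node (ligament and muscle
        bone-side attachments), the node index.  Ground points and hip
        centers are spatial points and do not appear here.
    elem_bone : (m,) int array
        Bone id per tetrahedron (index into :data:`BONE_NAMES`).
    """

    nodes: np.ndarray
    tets: np.ndarray
    patches: dict[str, np.ndarray]
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)
    landmark_nodes: dict[str, int] = field(default_factory=dict)
    elem_bone: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return int(self.nodes.shape[0])

    @property
    def n_elements(self) -> int:
        return int(self.tets.shape[0])

    def patch_nodes(self, name: str) -> np.ndarray:
        """Unique node indices of a named surface patch."""
        if name not in self.patches:
            raise MeshError(f"unknown surface patch {name!r}")
        return np.unique(self.patches[name])

    def validate(self, required=REQUIRED_PATCHES) -> None:
        """Check structural invariants; raise :class:`MeshError` on failure."""
        missing = [p for p in required if p not in self.patches]
        if missing:
            raise MeshError(
                "mesh is missing required surface patches: " + ", ".join(missing)
            )
        vols = tet_volumes(self.nodes, self.tets)
        bad = np.flatnonzero(vols <= 0.0)
        if bad.size:
            raise MeshError(f"non-positively-oriented tetrahedra at indices {bad[:5].tolist()}")
        face_owner = boundary_face_owners(self.tets)
        for name, tris in self.patches.items():
            for tri in tris:
                if tuple(sorted(tri)) not in face_owner:
                    raise MeshError(
                        f"patch {name!r} contains triangle {tri.tolist()} that is "
                        "not a boundary face of exactly one tetrahedron"
                    )
        if len(self.landmarks) != len(set(self.landmarks)):
            raise MeshError("landmark names are not unique")


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for right-handed ordering)."""
    a, b, c, d = (nodes[tets[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0


def fix_orientation(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Return connectivity with all tetrahedra positively oriented."""
    tets = tets.copy()
    neg = tet_volumes(nodes, tets) < 0.0
    tets[neg, 2], tets[neg, 3] = tets[neg, 3].copy(), tets[neg, 2].copy()
    return tets


def tet_faces(tets: np.ndarray) -> np.ndarray:
    """All (4m, 3) faces of the tetrahedra, outward-oriented per owning tet."""
    # face i is opposite node i; ordering gives outward normal for a
    # positively oriented tet
    f = np.concatenate(
        [
            tets[:, [1, 2, 3]],
            tets[:, [0, 3, 2]],
            tets[:, [0, 1, 3]],
            tets[:, [0, 2, 1]],
        ]
    )
    return f


def boundary_face_owners(tets: np.ndarray) -> dict[tuple[int, int, int], int]:
    """Map sorted boundary-face node tuples to the owning tetra index.

    A boundary face belongs to exactly one tetrahedron.
    """
    faces = tet_faces(tets)
    owners = np.tile(np.arange(tets.shape[0]), 4)
    key = np.sort(faces, axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    key = key[order]
    owners = owners[order]
    out: dict[tuple[int, int, int], int] = {}
    i = 0
    n = key.shape[0]
    while i < n:
        j = i + 1
        while j < n and np.array_equal(key[j], key[i]):
            j += 1
        if j - i == 1:  # unshared -> boundary
            out[tuple(int(v) for v in key[i])] = int(owners[i])
        i = j
    return out


def boundary_nodes(tets: np.ndarray) -> np.ndarray:
    """Node indices lying on the exterior surface."""
    faces = np.array(sorted(boundary_face_owners(tets)), dtype=int)
    if faces.size == 0:
        return np.empty(0, dtype=int)
    return np.unique(faces)


def orient_patch_outward(nodes: np.ndarray, tets: np.ndarray,
                         tris: np.ndarray) -> np.ndarray:
    """Reorder patch triangles so their normals point out of the bone."""
    owners = boundary_face_owners(tets)
    out = tris.copy()
    for t, tri in enumerate(tris):
        key = tuple(sorted(int(v) for v in tri))
        if key not in owners:
            raise MeshError(f"triangle {tri.tolist()} is not a boundary face")
        tet = tets[owners[key]]
        opp = [v for v in tet if v not in key][0]
        a, b, c = nodes[tri[0]], nodes[tri[1]], nodes[tri[2]]
        n = np.cross(b - a, c - a)
        if np.dot(n, nodes[opp] - a) > 0:  # normal points inward: flip
            out[t, 1], out[t, 2] = tri[2], tri[1]
    return out


def triangle_areas(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    a, b, c = nodes[tris[:, 0]], nodes[tris[:, 1]], nodes[tris[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def triangle_normals(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Unit normals of oriented triangles."""
    a, b, c = nodes[tris[:, 0]], nodes[tris[:, 1]], nodes[tris[:, 2]]
    n = np.cross(b - a, c - a)
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def merge_meshes(parts: list[tuple[np.ndarray, np.ndarray]]):
    """Concatenate (nodes, tets) pairs, offsetting connectivity.

    Returns (nodes, tets, node_offsets, elem_bone).
    """
    nodes = []
    tets = []
    bone = []
    offsets = []
    off = 0
    for i, (nd, tt) in enumerate(parts):
        offsets.append(off)
        nodes.append(nd)
        tets.append(tt + off)
        bone.append(np.full(tt.shape[0], i, dtype=int))
        off += nd.shape[0]
    return (
        np.concatenate(nodes),
        np.concatenate(tets),
        np.array(offsets, dtype=int),
        np.concatenate(bone),
    )
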