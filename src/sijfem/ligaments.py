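"""Tension-only, pre-loaded spring network for ligaments and muscles.

Seven ligament groups stabilize each sacroiliac joint, the pubic symphysis
bridges the two ilia, and the two gluteal muscles are modelled as passive
springs anchored at fixed spatial points (the reduced single-point femoral
attachment).  Pre-tension is produced by shortening the stress-free
reference length below the installed length: a spring of stiffness k held
at its installed length L_inst with reference length
L_ref = L_inst - F_pre / k carries exactly F_pre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

#: Ligament-group stiffness roster (N/mm), total per group.
#: The pubic symphysis is modelled as two parallel fibers of 500 N/mm.
LIGAMENT_STIFFNESS = {
    "ASL": 700.0,
    "ISL": 2800.0,
    "LPSL": 1000.0,
    "PSL": 400.0,
    "SS": 1400.0,
    "ST": 1500.0,
    "PS": 1000.0,
    "gluteus_maximus": 344.0,
    "gluteus_medius": 779.0,
}

#: Number of fibers per group (stiffness split equally across fibers).
FIBER_COUNT = {"ASL": 3, "ISL": 3, "PSL": 3, "PS": 2}

DEFAULT_PRETENSION = 118.0  # N, per ligament group

MUSCLES = ("gluteus_maximus", "gluteus_medius")


class LigamentError(ValueError):
    pass


@dataclass
class LigamentSpec:
    """One ligament or muscle group: stiffness, fibers, pre-tension."""

    name: str
    stiffness: float                       # total group stiffness (N/mm)
    fibers: list[tuple[str, str]]          # landmark-name endpoint pairs
    pretension: float = DEFAULT_PRETENSION  # F_pre for the whole group (N)
    pretension_enabled: bool = True

    def __post_init__(self):
        if self.stiffness <= 0:
            raise LigamentError(f"{self.name}: stiffness must be > 0")
        if self.pretension < 0:
            raise LigamentError(f"{self.name}: pre-tension must be >= 0")
        if not self.fibers:
            raise LigamentError(f"{self.name}: at least one fiber required")


@dataclass
class SpringElementSet:
    """Flat arrays over all fibers of one or more installed groups.

    Endpoint a/b are mesh nodes (index >= 0) or fixed spatial points
    (index -1, coordinates in ``point_a``/``point_b``).
    """

    names: list[str] = field(default_factory=list)
    node_a: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    node_b: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    point_a: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    point_b: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    stiffness: np.ndarray = field(default_factory=lambda: np.empty(0))
    length_installed: np.ndarray = field(default_factory=lambda: np.empty(0))
    length_reference: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_fibers(self) -> int:
        return int(self.stiffness.shape[0])

    def endpoint_positions(self, nodes: np.ndarray, u: np.ndarray | None = None):
        """Current endpoint coordinates given nodal displacements ``u``."""
        x = nodes if u is None else nodes + u
        xa = np.where(self.node_a[:, None] >= 0, x[self.node_a], self.point_a)
        xb = np.where(self.node_b[:, None] >= 0, x[self.node_b], self.point_b)
        return xa, xb

    @staticmethod
    def concatenate(sets: list["SpringElementSet"]) -> "SpringElementSet":
        out = SpringElementSet()
        out.names = sum((s.names for s in sets), [])
        for f in ("node_a", "node_b", "point_a", "point_b", "stiffness",
                  "length_installed", "length_reference"):
            setattr(out, f, np.concatenate([getattr(s, f) for s in sets]))
        return out


def pretension_reference_length(k: float, length_installed: float,
                                pretension: float) -> float:
    """Reference length producing ``pretension`` at the installed length."""
    if k <= 0 or length_installed <= 0:
        raise LigamentError("stiffness and installed length must be > 0")
    if pretension < 0:
        raise LigamentError("pre-tension must be >= 0")
    shortening = pretension / k
    if shortening >= length_installed:
        raise LigamentError(
            f"unphysical shortening: F_pre/k = {shortening:.3g} mm >= "
            f"installed length {length_installed:.3g} mm"
        )
    return length_installed - shortening


def spring_axial_force(length, length_reference, k):
    """Tension-only axial force: k * (L - L_ref) when taut, else 0."""
    return np.maximum(0.0, np.asarray(k) * (np.asarray(length) - np.asarray(length_reference)))


def install_ligament(spec: LigamentSpec, mesh) -> SpringElementSet:
    """Resolve fiber endpoints against mesh landmarks and set lengths.

    The group stiffness and pre-tension are split equally among fibers.
    Landmarks snapped to mesh nodes attach to those nodes; other landmarks
    (muscle ground points) become fixed spatial endpoints.
    """
    s = SpringElementSet()
    nf = len(spec.fibers)
    k_fiber = spec.stiffness / nf
    f_pre = spec.pretension / nf if spec.pretension_enabled else 0.0

    na, nb, pa, pb, L0, Lr = [], [], [], [], [], []
    for i, (a, b) in enumerate(spec.fibers):
        for lm in (a, b):
            if lm not in mesh.landmarks:
                raise LigamentError(
                    f"ligament {spec.name!r}: landmark {lm!r} not found in mesh"
                )
        xa, xb = mesh.landmarks[a], mesh.landmarks[b]
        na.append(mesh.landmark_nodes.get(a, -1))
        nb.append(mesh.landmark_nodes.get(b, -1))
        pa.append(xa)
        pb.append(xb)
        L = float(np.linalg.norm(xb - xa))
        if L <= 0:
            raise LigamentError(f"ligament {spec.name!r}: zero-length fiber {i}")
        L0.append(L)
        Lr.append(pretension_reference_length(k_fiber, L, f_pre))
        s.names.append(f"{spec.name}[{i}]")

    s.node_a = np.array(na, dtype=int)
    s.node_b = np.array(nb, dtype=int)
    s.point_a = np.array(pa, dtype=float)
    s.point_b = np.array(pb, dtype=float)
    s.stiffness = np.full(nf, k_fiber)
    s.length_installed = np.array(L0)
    s.length_reference = np.array(Lr)
    return s


def default_ligament_specs(
    pretension: float = DEFAULT_PRETENSION,
    muscle_pretension: float = 0.0,
    include_muscles: bool = True,
    pretension_enabled: bool = True,
) -> list[LigamentSpec]:
    """The full bilateral roster with default stiffnesses and fibers."""
    specs = []
    for side in ("left", "right"):
        for name in ("ASL", "ISL", "PSL"):
            fibers = [
                (f"{name}_{side}_sacrum_{i}", f"{name}_{side}_ilium_{i}")
                for i in range(FIBER_COUNT[name])
            ]
            specs.append(LigamentSpec(f"{name}_{side}", LIGAMENT_STIFFNESS[name],
                                      fibers, pretension, pretension_enabled))
        for name in ("LPSL", "SS", "ST"):
            fibers = [(f"{name}_{side}_sacrum_0", f"{name}_{side}_ilium_0")]
            specs.append(LigamentSpec(f"{name}_{side}", LIGAMENT_STIFFNESS[name],
                                      fibers, pretension, pretension_enabled))
        if include_muscles:
            for name in MUSCLES:
                fibers = [(f"{name}_{side}_pelvis_0", f"gluteal_ground_{side}")]
                specs.append(
                    LigamentSpec(f"{name}_{side}", LIGAMENT_STIFFNESS[name],
                                 fibers, muscle_pretension, pretension_enabled)
                )
    specs.append(
        LigamentSpec(
            "PS", LIGAMENT_STIFFNESS["PS"],
            [(f"PS_left_{i}", f"PS_right_{i}") for i in range(FIBER_COUNT["PS"])],
            pretension, pretension_enabled,
        )
    )
    return specs


def install_all(specs: list[LigamentSpec], mesh) -> SpringElementSet:
    return SpringElementSet.concatenate([install_ligament(s, mesh) for s in specs])


def spring_forces(
    springs: SpringElementSet,
    nodes: np.ndarray,
    u: np.ndarray,
    tension_only: bool = True,
    geometric: bool = True,
):
    """Per-fiber axial forces and current unit directions a -> b.

    With ``geometric`` disabled the fiber direction is frozen at the
    reference configuration and the length change linearized along it.
    """
    xa0, xb0 = springs.endpoint_positions(nodes)
    d0 = xb0 - xa0
    L0 = np.linalg.norm(d0, axis=1)
    if np.any(L0 <= 0):
        raise LigamentError("zero-length fiber in reference configuration")
    n0 = d0 / L0[:, None]
    if geometric:
        xa, xb = springs.endpoint_positions(nodes, u)
        d = xb - xa
        L = np.linalg.norm(d, axis=1)
        if np.any(L <= 0):
            raise LigamentError("zero-length fiber in current configuration")
        n = d / L[:, None]
    else:
        ua = np.where(springs.node_a[:, None] >= 0, u[np.maximum(springs.node_a, 0)], 0.0)
        ub = np.where(springs.node_b[:, None] >= 0, u[np.maximum(springs.node_b, 0)], 0.0)
        L = L0 + np.einsum("ij,ij->i", ub - ua, n0)
        n = n0
    elong = L - springs.length_reference
    F = springs.stiffness * elong
    if tension_only:
        F = np.maximum(F, 0.0)
    return F, n, L


def spring_residual_and_tangent(
    springs: SpringElementSet,
    nodes: np.ndarray,
    u: np.ndarray,
    n_nodes: int,
    tension_only: bool = True,
    geometric: bool = True,
):
    """Nodal force vector applied by the springs and its exact tangent.

    Returns ``(f, K)`` with ``f`` of shape (3 n_nodes,) holding forces the
    springs exert on the mesh nodes, and ``K = -df/du`` as a sparse matrix
    (positive semi-definite for taut fibers), so the structural tangent is
    ``K_bone + K``.
    """
    F, n, L = spring_forces(springs, nodes, u, tension_only, geometric)
    if tension_only:
        # a fiber exactly at F = 0 still contributes material stiffness
        # when taut-at-zero (L == L_ref); helps tangent conditioning
        active = L >= springs.length_reference
    else:
        active = np.ones(springs.n_fibers, dtype=bool)

    f = np.zeros((n_nodes, 3))
    rows, cols, vals = [], [], []
    I3 = np.eye(3)
    for i in range(springs.n_fibers):
        ni = n[i]
        Fi = F[i]
        # force on node a points toward b (tension), on b toward a
        for node, sign in ((springs.node_a[i], +1.0), (springs.node_b[i], -1.0)):
            if node >= 0:
                f[node] += sign * Fi * ni
        if not active[i]:
            continue
        k_mat = springs.stiffness[i] * np.outer(ni, ni)
        if geometric:
            k_geo = (Fi / L[i]) * (I3 - np.outer(ni, ni))
            kb = k_mat + k_geo
        else:
            kb = k_mat
        ends = [(springs.node_a[i], +1.0), (springs.node_b[i], -1.0)]
        for na_, sa in ends:
            if na_ < 0:
                continue
            for nb_, sb in ends:
                if nb_ < 0:
                    continue
                blk = sa * sb * kb
                for r in range(3):
                    for c in range(3):
                        rows.append(3 * na_ + r)
                        cols.append(3 * nb_ + c)
                        vals.append(blk[r, c])
    K = sp.coo_matrix(
        (vals, (rows, cols)), shape=(3 * n_nodes, 3 * n_nodes)
    ).tocsr()
    return f.ravel(), K
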