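"""Pressure-overclosure contact with regularized Coulomb friction.

Normal behaviour follows a softened pressure-clearance law anchored at two
points: zero pressure at a clearance equal to the cartilage thickness c0,
and a pressure equal to the cartilage Young's modulus p0 at zero clearance.
Between the anchors the exponential law

    p(g) = p0 * (exp((c0 - g)/c0) - 1) / (e - 1),   g < c0

decays smoothly to zero at g = c0; a linear law sharing both anchors is
available for the contact-type perturbation study.  Tangential behaviour is
penalty-regularized Coulomb friction with coefficient mu.

Gap detection is node-to-surface: each follower node is projected onto the
closest point of the target triangulation and the gap measured along the
target outward normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

E_MINUS_1 = np.e - 1.0


class ContactError(ValueError):
    pass


@dataclass(frozen=True)
class ContactLaw:
    """Normal/tangential contact constitutive parameters.

    c0 : clearance at zero pressure (mm) — the cartilage thickness.
    p0 : pressure at zero clearance (MPa) — the cartilage modulus.
    mu : Coulomb friction coefficient.
    law : "exponential" or "linear".
    stick_stiffness : tangential penalty (MPa per mm of slip).
    """

    c0: float
    p0: float
    mu: float = 0.4
    law: str = "exponential"
    stick_stiffness: float = 100.0

    def __post_init__(self):
        if self.c0 <= 0 or self.p0 <= 0:
            raise ContactError("c0 and p0 must be > 0")
        if self.mu < 0:
            raise ContactError("mu must be >= 0")
        if self.law not in ("exponential", "linear"):
            raise ContactError(f"unknown contact law {self.law!r}")

    def pressure(self, gap):
        if self.law == "exponential":
            return pressure_overclosure_exponential(gap, self.c0, self.p0)
        return pressure_overclosure_linear(gap, self.c0, self.p0)

    def pressure_slope(self, gap):
        """dp/dg (non-positive)."""
        g = np.asarray(gap, dtype=float)
        if self.law == "exponential":
            s = -self.p0 / (self.c0 * E_MINUS_1) * np.exp((self.c0 - g) / self.c0)
        else:
            s = np.full_like(g, -self.p0 / self.c0)
        return np.where(g < self.c0, s, 0.0)


#: Default laws from the study set-up: SIJ cartilage 3 mm / 54 MPa,
#: pubic symphysis 4 mm / 5 MPa, friction 0.4.
SIJ_LAW = ContactLaw(c0=3.0, p0=54.0, mu=0.4)
PUBIC_LAW = ContactLaw(c0=4.0, p0=5.0, mu=0.4)


def pressure_overclosure_exponential(gap, c0: float, p0: float):
    """Exponential pressure-overclosure: p0 at g=0, 0 at g=c0, smooth decay."""
    if c0 <= 0 or p0 <= 0:
        raise ContactError("c0 and p0 must be > 0")
    g = np.asarray(gap, dtype=float)
    p = p0 * (np.exp((c0 - g) / c0) - 1.0) / E_MINUS_1
    return np.where(g < c0, p, 0.0)


def pressure_overclosure_linear(gap, c0: float, p0: float):
    """Linear pressure-overclosure sharing the anchors of the exponential law."""
    if c0 <= 0 or p0 <= 0:
        raise ContactError("c0 and p0 must be > 0")
    g = np.asarray(gap, dtype=float)
    return p0 * np.maximum(0.0, c0 - g) / c0


def friction_traction(slip, pressure, mu: float, stick_stiffness: float = 100.0):
    """Penalty-regularized Coulomb traction opposing the slip vector.

    |t| = min(k_t |s|, mu p); zero when the contact is open (p = 0).
    """
    s = np.atleast_2d(np.asarray(slip, dtype=float))
    p = np.atleast_1d(np.asarray(pressure, dtype=float))
    mag = np.linalg.norm(s, axis=1)
    lim = np.minimum(stick_stiffness * mag, mu * p)
    with np.errstate(invalid="ignore", divide="ignore"):
        direction = np.where(mag[:, None] > 0, s / np.where(mag == 0, 1.0, mag)[:, None], 0.0)
    t = -lim[:, None] * direction
    if np.asarray(slip).ndim == 1:
        return t[0]
    return t


# ---------------------------------------------------------------------------
# node-to-surface gap detection


def _closest_point_triangles(p, a, b, c):
    """Vectorized closest point on triangles (a,b,c) for each point p.

    All arrays (n, 3).  Returns (proj, bary) with barycentric coordinates
    (w_a, w_b, w_c).  Ericson's region-based algorithm.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    bary = np.zeros_like(p)

    # default: interior
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    bary[:, 0] = 1.0 - v - w
    bary[:, 1] = v
    bary[:, 2] = w

    # edge AB region
    t_ab = np.clip(d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3), 0.0, 1.0)
    m_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    # edge AC region
    t_ac = np.clip(d2 / np.where(d2 - d6 == 0, 1.0, d2 - d6), 0.0, 1.0)
    m_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    # edge BC region
    num_bc = d4 - d3
    den_bc = (d4 - d3) + (d5 - d6)
    t_bc = np.clip(num_bc / np.where(den_bc == 0, 1.0, den_bc), 0.0, 1.0)
    m_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    # vertex regions
    m_a = (d1 <= 0) & (d2 <= 0)
    m_b = (d3 >= 0) & (d4 <= d3)
    m_c = (d6 >= 0) & (d5 <= d6)

    for mask, w_abc in (
        (m_bc, np.stack([np.zeros_like(t_bc), 1 - t_bc, t_bc], axis=1)),
        (m_ac, np.stack([1 - t_ac, np.zeros_like(t_ac), t_ac], axis=1)),
        (m_ab, np.stack([1 - t_ab, t_ab, np.zeros_like(t_ab)], axis=1)),
        (m_c, np.tile([0.0, 0.0, 1.0], (len(p), 1))),
        (m_b, np.tile([0.0, 1.0, 0.0], (len(p), 1))),
        (m_a, np.tile([1.0, 0.0, 0.0], (len(p), 1))),
    ):
        bary = np.where(mask[:, None], w_abc, bary)

    proj = bary[:, 0:1] * a + bary[:, 1:2] * b + bary[:, 2:3] * c
    return proj, bary


def detect_gaps(
    points: np.ndarray,
    target_nodes: np.ndarray,
    target_tris: np.ndarray,
    search_radius: float = 25.0,
):
    """Project follower points onto the target patch.

    Returns a dict of arrays over follower points: ``gap`` (signed distance
    along the target outward normal at the closest point, positive =
    separation), ``proj`` (closest points), ``tri`` (triangle index, ties
    broken by lowest index), ``bary`` (barycentric weights) and ``active``
    (False where no projection lies within ``search_radius``).
    """
    if target_tris.shape[0] == 0:
        raise ContactError("target patch has no triangles")
    a = target_nodes[target_tris[:, 0]]
    b = target_nodes[target_tris[:, 1]]
    c = target_nodes[target_tris[:, 2]]
    nrm = np.cross(b - a, c - a)
    areas2 = np.linalg.norm(nrm, axis=1)
    if np.any(areas2 <= 0):
        raise ContactError("degenerate triangle in target patch")
    normals = nrm / areas2[:, None]
    # vertex-averaged normal field (area-weighted), interpolated at the
    # projection point: keeps the gap and force direction continuous when
    # the projection crosses facet boundaries
    vnorm = np.zeros_like(target_nodes, dtype=float)
    for j in range(3):
        np.add.at(vnorm, target_tris[:, j], nrm)
    norms = np.linalg.norm(vnorm, axis=1, keepdims=True)
    vnorm = np.divide(vnorm, norms, out=np.zeros_like(vnorm), where=norms > 0)

    npts, ntri = points.shape[0], target_tris.shape[0]
    P = np.repeat(points, ntri, axis=0)
    A = np.tile(a, (npts, 1))
    B = np.tile(b, (npts, 1))
    C = np.tile(c, (npts, 1))
    proj, bary = _closest_point_triangles(P, A, B, C)
    d2 = np.einsum("ij,ij->i", P - proj, P - proj).reshape(npts, ntri)
    tri = np.argmin(d2, axis=1)  # argmin keeps the lowest index on ties
    rows = np.arange(npts)
    proj = proj.reshape(npts, ntri, 3)[rows, tri]
    bary = bary.reshape(npts, ntri, 3)[rows, tri]
    dist = np.sqrt(d2[rows, tri])
    n_at = np.einsum("ij,ijk->ik", bary, vnorm[target_tris[tri]])
    nn = np.linalg.norm(n_at, axis=1, keepdims=True)
    n_at = np.where(nn > 0, n_at / np.where(nn == 0, 1.0, nn), normals[tri])
    gap = np.einsum("ij,ij->i", points - proj, n_at)
    return {
        "gap": gap,
        "proj": proj,
        "tri": tri,
        "bary": bary,
        "normal": n_at,
        "active": dist <= search_radius,
    }


@dataclass
class ContactPairDef:
    """A follower/target patch pairing with its constitutive law.

    ``area_scale`` scales the follower tributary areas; a mirror-symmetric
    two-pass pairing uses both directions at half area each.
    """

    follower: str
    target: str
    law: ContactLaw
    search_radius: float = 25.0
    area_scale: float = 1.0
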