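"""Output quantities: surface stress summaries and relative joint motion.

Stress is summarized over the elements owning a surface patch's triangles
(mean, standard deviation, median and the linearly interpolated 99th
percentile of the element von Mises stress).  Relative joint motion is
measured by least-squares rigid-transform fits (Kabsch) of the two patch
displacement fields; the relative translation is evaluated at the joint-gap
centroid to make it independent of the coordinate origin, and the rotation
is reported as the total angle of the relative rotation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .fe import SolutionState
from .mesh import MeshError, TetMesh, boundary_face_owners


class PostprocError(ValueError):
    pass


@dataclass
class StressSummary:
    surface: str
    mean: float
    sd: float
    median: float
    p99: float
    n_elements: int


@dataclass
class JointKinematics:
    side: str
    translation: float      # mm, magnitude at the joint-gap centroid
    rotation: float         # deg, total angle of the relative rotation
    relative_rotation: np.ndarray    # (3,3)
    relative_translation: np.ndarray  # (3,)


def surface_elements(mesh: TetMesh, surface: str) -> np.ndarray:
    """Indices of the tetrahedra owning a patch's triangles."""
    if surface not in mesh.patches:
        raise PostprocError(f"unknown surface {surface!r}")
    tris = mesh.patches[surface]
    if len(tris) == 0:
        raise PostprocError(f"surface {surface!r} is empty")
    owners = boundary_face_owners(mesh.tets)
    out = []
    for tri in tris:
        key = tuple(sorted(int(v) for v in tri))
        if key not in owners:
            raise MeshError(f"patch triangle {tri.tolist()} is not a boundary face")
        out.append(owners[key])
    return np.unique(out)


def surface_stress_summary(
    state: SolutionState, mesh: TetMesh, surface: str
) -> StressSummary:
    """Von Mises statistics over the elements owning the surface triangles."""
    elems = surface_elements(mesh, surface)
    vm = state.stress_von_mises[elems]
    return StressSummary(
        surface=surface,
        mean=float(np.mean(vm)),
        sd=float(np.std(vm)),
        median=float(np.median(vm)),
        p99=float(np.percentile(vm, 99)),  # linear-interpolation percentile
        n_elements=int(len(elems)),
    )


def _rigid_fit(X: np.ndarray, U: np.ndarray):
    """Least-squares rigid transform (R, t) mapping X to X + U."""
    Y = X + U
    xb, yb = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - xb, Y - yb
    sv = np.linalg.svd(Xc, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise PostprocError("patch nodes are (nearly) collinear; rigid fit is rank-deficient")
    H = Xc.T @ Yc
    Uw, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ Uw.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ Uw.T
    t = yb - R @ xb
    return R, t


def relative_joint_motion(
    state: SolutionState, mesh: TetMesh, sacrum_patch: str, ilium_patch: str,
    side: str = "",
) -> JointKinematics:
    """Relative rigid motion of the ilium patch with respect to the sacrum
    patch, from best-fit rigid transforms of their displacement fields."""
    for p in (sacrum_patch, ilium_patch):
        if p not in mesh.patches:
            raise PostprocError(f"unknown surface {p!r}")
    ns = mesh.patch_nodes(sacrum_patch)
    ni = mesh.patch_nodes(ilium_patch)
    Rs, ts = _rigid_fit(mesh.nodes[ns], state.u[ns])
    Ri, ti = _rigid_fit(mesh.nodes[ni], state.u[ni])
    # T_rel = T_ilium o T_sacrum^-1
    R_rel = Ri @ Rs.T
    t_rel = ti - R_rel @ ts
    centroid = 0.5 * (mesh.nodes[ns].mean(axis=0) + mesh.nodes[ni].mean(axis=0))
    d = R_rel @ centroid + t_rel - centroid
    cos = np.clip((np.trace(R_rel) - 1.0) / 2.0, -1.0, 1.0)
    return JointKinematics(
        side=side,
        translation=float(np.linalg.norm(d)),
        rotation=float(np.degrees(np.arccos(cos))),
        relative_rotation=R_rel,
        relative_translation=t_rel,
    )


def joint_kinematics_both_sides(state: SolutionState, mesh: TetMesh):
    return {
        side: relative_joint_motion(
            state, mesh, f"sij_sacrum_{side}", f"sij_ilium_{side}", side=side
        )
        for side in ("left", "right")
    }


# ---------------------------------------------------------------------------
# reports


def config_hash(config: dict) -> str:
    """Stable hash of a configuration dict (invariant to key order)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(
    stress_rows: list[dict],
    kinematics_rows: list[dict],
    out_dir,
    metadata: dict | None = None,
) -> dict:
    """Write stress/kinematics tables as wide CSVs plus a JSON metadata blob.

    ``stress_rows``: dicts with keys variant, surface, scenario, mean, sd,
    median, p99.  ``kinematics_rows``: dicts with variant, side, scenario,
    translation, rotation.  Tables are pivoted to rows = (variant, surface
    or side), columns = scenarios, holding the mean stress / translation /
    rotation; the long-form tables are written alongside.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    sdf = pd.DataFrame(stress_rows)
    kdf = pd.DataFrame(kinematics_rows)
    sdf.to_csv(out / "stress_long.csv", index=False)
    kdf.to_csv(out / "kinematics_long.csv", index=False)
    files["stress_long"] = str(out / "stress_long.csv")
    files["kinematics_long"] = str(out / "kinematics_long.csv")

    index = ["variant", "surface"] if "variant" in sdf.columns else ["surface"]
    wide = sdf.pivot_table(index=index, columns="scenario", values="mean", sort=False)
    wide = wide[[c for c in dict.fromkeys(sdf["scenario"])]]  # preserve order
    wide.to_csv(out / "stress_mean.csv")
    files["stress_mean"] = str(out / "stress_mean.csv")

    kindex = ["variant", "side"] if "variant" in kdf.columns else ["side"]
    for value in ("translation", "rotation"):
        w = kdf.pivot_table(index=kindex, columns="scenario", values=value, sort=False)
        w = w[[c for c in dict.fromkeys(kdf["scenario"])]]
        w.to_csv(out / f"kinematics_{value}.csv")
        files[f"kinematics_{value}"] = str(out / f"kinematics_{value}.csv")

    meta = dict(metadata or {})
    meta["files"] = files
    with open(out / "report.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
    files["report"] = str(out / "report.json")
    return files
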