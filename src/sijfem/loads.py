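"""Load scenarios, synthetic gait curves and boundary conditions.

Eight generic scenarios apply the extreme gait load components
(Fx = 600 N medio-lateral, Fy = 1200 N antero-posterior, Fz = 2400 N
cranial-caudal) per axis or combined, unilaterally (left side) or
bilaterally.  "Symmetric" means mirror-symmetric about the mid-sagittal
plane: the right-side force is the x-reflection of the left-side force.

The gait generator produces a smooth, seeded, periodic 3-component hip
force curve whose per-component absolute extremes equal the configured
peaks, with the five gait events (IHS, CTO, swing, CHS, ITO) marked; the
five quasi-static phase loads are the curve values at those events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fe import Coupling, FEModel
from .mesh import MeshError

#: Extreme per-axis load components (N).
PEAK_LOADS = (600.0, 1200.0, 2400.0)

#: Gait events as % of the gait cycle, in phase order.
GAIT_EVENTS = {"IHS": 2.0, "CTO": 12.0, "swing": 35.0, "CHS": 50.0, "ITO": 62.0}

_MIRROR = np.array([-1.0, 1.0, 1.0])


class LoadError(ValueError):
    pass


@dataclass(frozen=True)
class LoadCase:
    """A static per-side hip load in the local hip frames (N)."""

    name: str
    left: tuple[float, float, float]
    right: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: float = 1.0

    def __post_init__(self):
        if self.scale <= 0:
            raise LoadError("body-weight scale factor must be > 0")

    def side_forces(self) -> dict[str, np.ndarray]:
        return {
            "left": self.scale * np.asarray(self.left, dtype=float),
            "right": self.scale * np.asarray(self.right, dtype=float),
        }

    def scaled(self, factor: float) -> "LoadCase":
        return LoadCase(self.name, self.left, self.right, self.scale * factor)


def generic_scenarios(peaks=PEAK_LOADS) -> list[LoadCase]:
    """The 8 generic scenarios: unilateral/symmetric x, y, z and xyz."""
    fx, fy, fz = peaks
    # left-side force per axis: medial (-x on the left side), anterior, cranial
    axis_force = {"x": (-fx, 0.0, 0.0), "y": (0.0, fy, 0.0), "z": (0.0, 0.0, fz)}
    combined = (-fx, fy, fz)
    cases = []
    for ax, f in axis_force.items():
        cases.append(LoadCase(f"unilateral_{ax}", left=f))
    for ax, f in axis_force.items():
        cases.append(LoadCase(f"symmetric_{ax}", left=f, right=tuple(_MIRROR * f)))
    cases.append(LoadCase("unilateral_xyz", left=combined))
    cases.append(
        LoadCase("symmetric_xyz", left=combined, right=tuple(_MIRROR * combined))
    )
    return cases


@dataclass
class GaitCurve:
    """Time-resolved 3-component hip force over one gait cycle."""

    time_pct: np.ndarray                  # (s,) % of gait cycle, ascending
    forces: np.ndarray                    # (s, 3) N
    events: dict[str, float] = field(default_factory=dict)  # name -> % cycle

    def value_at(self, pct: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.time_pct - pct)))
        return self.forces[i]


def synth_gait(seed: int = 0, peaks=PEAK_LOADS, n_samples: int = 200) -> GaitCurve:
    """Seeded synthetic gait curve with exact per-component peak magnitudes.

    The vertical component has the classic double-bump stance shape with
    peaks near contralateral toe-off and heel-strike; the shear components
    are low-order periodic shapes.  Seeded Fourier perturbations (5 %)
    individualize the curve; each component is then rescaled so its
    absolute maximum equals the configured peak exactly.
    """
    t = np.linspace(0.0, 100.0, n_samples, endpoint=False)
    ph = 2 * np.pi * t / 100.0
    rng = np.random.default_rng(seed)

    def bump(center, width):
        d = (t - center + 50.0) % 100.0 - 50.0
        return np.exp(-0.5 * (d / width) ** 2)

    base = np.zeros((n_samples, 3))
    # medio-lateral: medial (negative on the left) through stance
    base[:, 0] = -(0.8 * bump(GAIT_EVENTS["CTO"], 14.0) + bump(GAIT_EVENTS["CHS"], 16.0))
    # antero-posterior: braking/propulsion alternation
    base[:, 1] = bump(GAIT_EVENTS["CHS"], 12.0) - 0.6 * bump(85.0, 12.0) + 0.4 * bump(
        GAIT_EVENTS["IHS"], 8.0
    )
    # cranial-caudal: double-bump stance curve
    base[:, 2] = bump(GAIT_EVENTS["CTO"], 9.0) + 0.95 * bump(GAIT_EVENTS["CHS"], 10.0)

    for c in range(3):
        pert = sum(
            rng.normal(0, 0.05) * np.sin((k + 1) * ph + rng.uniform(0, 2 * np.pi))
            for k in range(3)
        )
        base[:, c] = base[:, c] * (1.0 + pert)
        m = np.max(np.abs(base[:, c]))
        base[:, c] *= peaks[c] / m

    return GaitCurve(time_pct=t, forces=base, events=dict(GAIT_EVENTS))


_GAIT_COLUMNS = ("time_pct", "fx_n", "fy_n", "fz_n")


def write_gait_csv(curve: GaitCurve, path) -> None:
    df = pd.DataFrame(
        {
            "time_pct": curve.time_pct,
            "fx_n": curve.forces[:, 0],
            "fy_n": curve.forces[:, 1],
            "fz_n": curve.forces[:, 2],
        }
    )
    df.to_csv(path, index=False)


def load_gait_csv(path, events: dict[str, float] | None = None) -> GaitCurve:
    """Read a gait curve CSV (columns time_pct, fx_n, fy_n, fz_n).

    Events default to the standard five gait events when not supplied.
    """
    df = pd.read_csv(path)
    missing = [c for c in _GAIT_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"gait CSV is missing column(s): {', '.join(missing)}")
    return GaitCurve(
        time_pct=df["time_pct"].to_numpy(dtype=float),
        forces=df[["fx_n", "fy_n", "fz_n"]].to_numpy(dtype=float),
        events=dict(events) if events is not None else dict(GAIT_EVENTS),
    )


def extract_phase_loads(curve: GaitCurve, contralateral: str = "unloaded") -> list[LoadCase]:
    """One static LoadCase per marked gait event (ipsilateral = left).

    ``contralateral`` is "unloaded" (default) or "mirrored".
    """
    if not curve.events:
        raise LoadError("gait curve has no marked events")
    order = sorted(curve.events.items(), key=lambda kv: kv[1])
    cases = []
    for name, pct in order:
        f = tuple(curve.value_at(pct))
        right = tuple(_MIRROR * f) if contralateral == "mirrored" else (0.0, 0.0, 0.0)
        cases.append(LoadCase(f"gait_{name}", left=f, right=right))
    return cases


def apply_boundary_conditions(model: FEModel, hip_radius: float = 20.0) -> FEModel:
    """Fix the lumbosacral surface and install the per-side hip couplings.

    All nodes of the lumbosacral patch are fixed in all three DOF (the
    muscle ground points are fixed spatial points by construction).  The
    hip-center landmark of each side is tied to the nearby ilium surface
    nodes by a distributing coupling.
    """
    mesh = model.mesh
    if "lumbosacral" not in mesh.patches or len(mesh.patches["lumbosacral"]) == 0:
        raise MeshError("lumbosacral patch is empty; cannot fix the sacrum")
    model.fixed_nodes = mesh.patch_nodes("lumbosacral")

    from .mesh import boundary_nodes

    bnodes = boundary_nodes(mesh.tets)
    for side, bone_id in (("left", 1), ("right", 2)):
        lm = f"hip_center_{side}"
        if lm not in mesh.landmarks:
            raise MeshError(f"missing landmark {lm!r}")
        center = mesh.landmarks[lm]
        bone_nodes = np.unique(mesh.tets[mesh.elem_bone == bone_id])
        cand = np.intersect1d(bone_nodes, bnodes)
        d = np.linalg.norm(mesh.nodes[cand] - center, axis=1)
        sel = cand[d <= hip_radius]
        if sel.size < 3:
            sel = cand[np.argsort(d)[:6]]  # guarantee a well-posed coupling
        model.couplings[side] = Coupling(reference_point=center, nodes=sel)
    return model
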