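"""One-at-a-time sensitivity, perturbation and mesh-convergence studies.

The normalized sensitivity of an output O to a dimensionless input factor f
is the least-squares slope of the relative output change against the
factor change over the sweep points:

    s = slope of  (O(f) / O(f0) - 1)  versus  (f - f0)

with f0 the baseline factor.  A negative s means the output decreases as
the input grows.  For symmetric three-point sweeps this slope equals the
central finite difference.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fe import SolverError, solve_quasistatic
from .geometry import MorphologyParams, build_pelvis_mesh
from .loads import LoadCase, generic_scenarios
from .modeling import build_model
from .postproc import joint_kinematics_both_sides, surface_stress_summary

OUTPUT_NAMES = ("mean_stress", "mean_translation", "mean_rotation")

#: Sweep input name -> build_model keyword (load_intensity scales the load).
_INPUT_KEYWORDS = {
    "ligament_reference_length": "reference_length_scale",
    "ligament_stiffness": "stiffness_scale",
    "friction": "friction",
    "overclosure": "overclosure_scale",
    "attachment_shift": "attachment_shift",
}

#: Default sweep factor ranges of the study design.
DEFAULT_RANGES = {
    "ligament_reference_length": (0.998, 1.0),
    "ligament_stiffness": (0.6, 1.4),
    "load_intensity": (0.6, 1.4),
}


class SensitivityError(ValueError):
    pass


@dataclass
class SensitivityResult:
    input_name: str
    output_name: str
    sensitivity: float
    baseline_factor: float
    table: pd.DataFrame = field(repr=False, default=None)


def scenario_by_name(name: str) -> LoadCase:
    for c in generic_scenarios():
        if c.name == name:
            return c
    raise SensitivityError(f"unknown scenario {name!r}")


def model_outputs(sol, mesh) -> dict:
    """The three scalar outputs: mean ilium-surface stress (MPa), mean
    relative SIJ translation (mm) and rotation (deg) over both sides."""
    stress = np.mean(
        [
            surface_stress_summary(sol, mesh, f"sij_ilium_{side}").mean
            for side in ("left", "right")
        ]
    )
    kin = joint_kinematics_both_sides(sol, mesh)
    return {
        "mean_stress": float(stress),
        "mean_translation": float(np.mean([k.translation for k in kin.values()])),
        "mean_rotation": float(np.mean([k.rotation for k in kin.values()])),
    }


def solve_outputs(model, case: LoadCase) -> dict:
    sol = solve_quasistatic(model, case.side_forces())
    return model_outputs(sol, model.mesh)


def sweep_parameter(
    input_name: str,
    factors,
    scenario: str = "symmetric_xyz",
    model_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Solve once per factor with all other inputs at baseline.

    Returns a table with columns ``factor`` and the three outputs.  Any
    non-converged solve aborts the sweep, reporting the failing factor.
    """
    factors = list(factors)
    if len(factors) < 1:
        raise SensitivityError("at least one sweep factor required")
    model_kwargs = dict(model_kwargs or {})
    case = scenario if isinstance(scenario, LoadCase) else scenario_by_name(scenario)
    rows = []
    base_model = None
    for f in factors:
        try:
            if input_name == "load_intensity":
                if base_model is None:
                    base_model = build_model(**model_kwargs)
                out = solve_outputs(base_model, case.scaled(f))
            else:
                if input_name not in _INPUT_KEYWORDS:
                    raise SensitivityError(f"unknown sweep input {input_name!r}")
                kw = dict(model_kwargs)
                kw[_INPUT_KEYWORDS[input_name]] = f
                out = solve_outputs(build_model(**kw), case)
        except SolverError as exc:
            raise SensitivityError(
                f"sweep of {input_name!r} aborted: solve failed at factor {f}: {exc}"
            ) from exc
        rows.append({"factor": f, **out})
    return pd.DataFrame(rows)


def sensitivity(
    table: pd.DataFrame,
    input_name: str,
    output_name: str = "mean_translation",
    baseline_factor: float = 1.0,
) -> SensitivityResult:
    """Normalized sensitivity from a sweep table (least-squares slope)."""
    if len(table) < 2:
        raise SensitivityError("sweep needs at least 2 points")
    f = table["factor"].to_numpy(dtype=float)
    y = table[output_name].to_numpy(dtype=float)
    i0 = int(np.argmin(np.abs(f - baseline_factor)))
    y0 = y[i0]
    if y0 == 0.0:
        raise SensitivityError(
            f"baseline output {output_name!r} is zero; relative change undefined"
        )
    x = f - f[i0]
    rel = y / y0 - 1.0
    xc = x - x.mean()
    s = float(np.dot(xc, rel - rel.mean()) / np.dot(xc, xc))
    return SensitivityResult(
        input_name=input_name,
        output_name=output_name,
        sensitivity=s,
        baseline_factor=float(f[i0]),
        table=table,
    )


def sensitivities_all_outputs(table, input_name, baseline_factor=1.0) -> dict:
    return {
        out: sensitivity(table, input_name, out, baseline_factor).sensitivity
        for out in OUTPUT_NAMES
    }


# ---------------------------------------------------------------------------
# perturbation studies

PERTURBATIONS = (
    "attachment_shift_medial_10mm",
    "attachment_shift_lateral_20mm",
    "contact_linear_vs_exponential",
    "friction_0.2_to_0.6",
    "overclosure_scale",
)


def perturbation_study(
    which: str,
    scenario: str = "symmetric_xyz",
    model_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Percent change of each output relative to the default configuration.

    The perturbations mirror the study design: gluteal attachment shifts
    (10 mm medial / 20 mm lateral), linear instead of exponential SIJ
    contact, friction varied 0.2-0.6, and the overclosure (cartilage
    thickness surrogate) scaled by +-20 %.
    """
    model_kwargs = dict(model_kwargs or {})
    case = scenario_by_name(scenario)
    base = solve_outputs(build_model(**model_kwargs), case)

    if which == "attachment_shift_medial_10mm":
        variants = [("shift_-10mm", {"attachment_shift": -10.0})]
    elif which == "attachment_shift_lateral_20mm":
        variants = [("shift_+20mm", {"attachment_shift": +20.0})]
    elif which == "contact_linear_vs_exponential":
        variants = [("linear_contact", {"law_type": "linear"})]
    elif which == "friction_0.2_to_0.6":
        variants = [("mu_0.2", {"friction": 0.2}), ("mu_0.6", {"friction": 0.6})]
    elif which == "overclosure_scale":
        variants = [
            ("c0_x0.8", {"overclosure_scale": 0.8}),
            ("c0_x1.2", {"overclosure_scale": 1.2}),
        ]
    else:
        raise SensitivityError(f"unknown perturbation {which!r}")

    rows = [{"case": "baseline", **base,
             **{f"pct_{k}": 0.0 for k in OUTPUT_NAMES}}]
    for label, kw in variants:
        out = solve_outputs(build_model(**{**model_kwargs, **kw}), case)
        rows.append(
            {
                "case": label,
                **out,
                **{
                    f"pct_{k}": 100.0 * (out[k] - base[k]) / base[k]
                    if base[k] != 0 else np.nan
                    for k in OUTPUT_NAMES
                },
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mesh convergence


def convergence_study(
    params: MorphologyParams | None = None,
    levels=("coarse", "medium", "fine"),
    scenario: str = "symmetric_xyz",
    model_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Outputs per refinement level with relative differences to the finest
    level and solve-time ratios to the first level."""
    params = params or MorphologyParams()
    model_kwargs = dict(model_kwargs or {})
    case = scenario_by_name(scenario)
    rows = []
    for lev in levels:
        mesh = build_pelvis_mesh(params, lev)
        model = build_model(mesh=mesh, **model_kwargs)
        t0 = time.perf_counter()
        out = solve_outputs(model, case)
        dt = time.perf_counter() - t0
        rows.append({"level": lev, "n_elements": mesh.n_elements,
                     "solve_time": dt, **out})
    df = pd.DataFrame(rows)
    ref = df.iloc[-1]
    for k in OUTPUT_NAMES:
        df[f"reldiff_{k}"] = (df[k] - ref[k]).abs() / (abs(ref[k]) if ref[k] else 1.0)
    df["time_ratio"] = df["solve_time"] / df["solve_time"].iloc[0]
    return df
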