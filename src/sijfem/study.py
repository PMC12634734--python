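"""End-to-end study pipeline.

``run_study`` reproduces the study design on the synthetic geometry: for
each morphology variant it solves the 8 generic load scenarios and the 5
quasi-static gait phases, summarizes ilium surface stresses and relative
joint kinematics into wide CSV tables, runs the three one-at-a-time
sensitivity sweeps (ligament reference length, ligament stiffness, load
intensity) on the symmetric xyz scenario, and writes everything with a
provenance record (seed, config hash, package version).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from . import __version__
from .fe import SolverError, SolverSettings, solve_quasistatic
from .loads import extract_phase_loads, generic_scenarios, synth_gait
from .modeling import build_model
from .postproc import (
    config_hash,
    joint_kinematics_both_sides,
    surface_stress_summary,
    write_report,
)
from .sensitivity import (
    DEFAULT_RANGES,
    OUTPUT_NAMES,
    sensitivities_all_outputs,
    sweep_parameter,
)

_SCENARIO_NAMES = tuple(c.name for c in generic_scenarios())


class StudyError(RuntimeError):
    """A pipeline stage failed; partial results are preserved on disk."""


class StudyConfig(BaseModel):
    """Schema-validated study configuration."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    variants: list[str] = ["female_like", "male_like"]
    refinement: str = "coarse"
    scenarios: list[str] = list(_SCENARIO_NAMES)
    gait_phases: bool = True
    sensitivity: bool = True
    sweep_points: int = 3
    out_dir: str = "results/study"
    model: dict = {}          # extra build_model keyword arguments
    solver: dict = {}         # SolverSettings overrides

    @field_validator("scenarios")
    @classmethod
    def _known_scenarios(cls, v):
        unknown = [s for s in v if s not in _SCENARIO_NAMES]
        if unknown:
            raise ValueError(
                f"unknown scenario name(s): {unknown}; valid: {list(_SCENARIO_NAMES)}"
            )
        return v

    @field_validator("refinement")
    @classmethod
    def _known_refinement(cls, v):
        if v not in ("coarse", "medium", "fine"):
            raise ValueError(f"unknown refinement {v!r}")
        return v

    def settings(self) -> SolverSettings:
        return SolverSettings(**self.solver)

    def hash(self) -> str:
        return config_hash(self.model_dump())


def _sweep_factors(input_name: str, n: int) -> list[float]:
    lo, hi = DEFAULT_RANGES[input_name]
    baseline = 1.0
    pts = sorted({lo, hi, baseline} | {
        lo + (hi - lo) * i / (n - 1) for i in range(n)
    }) if n > 3 else sorted({lo, baseline, hi})
    return list(pts)


def run_study(config: StudyConfig) -> dict:
    """Run the full pipeline; returns row lists and written file paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stress_rows: list[dict] = []
    kin_rows: list[dict] = []
    sens_rows: list[dict] = []
    provenance = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "version": __version__,
        "config": config.model_dump(),
    }

    cases = [c for c in generic_scenarios() if c.name in config.scenarios]
    if config.gait_phases:
        cases = cases + extract_phase_loads(synth_gait(config.seed))

    for variant in config.variants:
        try:
            model = build_model(
                variant=variant,
                refinement=config.refinement,
                seed=config.seed,
                settings=config.settings(),
                **config.model,
            )
        except Exception as exc:
            _dump_partial(stress_rows, kin_rows, sens_rows, out, provenance)
            raise StudyError(f"model build failed for variant {variant!r}: {exc}")
        for case in cases:
            try:
                sol = solve_quasistatic(model, case.side_forces())
            except SolverError as exc:
                _dump_partial(stress_rows, kin_rows, sens_rows, out, provenance)
                raise StudyError(
                    f"solve failed: variant {variant!r}, scenario {case.name!r}: {exc}"
                )
            for side in ("left", "right"):
                summ = surface_stress_summary(sol, model.mesh, f"sij_ilium_{side}")
                stress_rows.append(
                    {
                        "variant": variant,
                        "surface": f"ilium_{side}",
                        "scenario": case.name,
                        "mean": summ.mean,
                        "sd": summ.sd,
                        "median": summ.median,
                        "p99": summ.p99,
                        "n_elements": summ.n_elements,
                    }
                )
            kin = joint_kinematics_both_sides(sol, model.mesh)
            for side, k in kin.items():
                kin_rows.append(
                    {
                        "variant": variant,
                        "side": side,
                        "scenario": case.name,
                        "translation": k.translation,
                        "rotation": k.rotation,
                    }
                )

        if config.sensitivity:
            mk = {
                "variant": variant,
                "refinement": config.refinement,
                "seed": config.seed,
                "settings": config.settings(),
                **config.model,
            }
            for input_name in DEFAULT_RANGES:
                try:
                    table = sweep_parameter(
                        input_name,
                        _sweep_factors(input_name, config.sweep_points),
                        scenario="symmetric_xyz",
                        model_kwargs=mk,
                    )
                except Exception as exc:
                    _dump_partial(stress_rows, kin_rows, sens_rows, out, provenance)
                    raise StudyError(
                        f"sensitivity sweep {input_name!r} failed for {variant!r}: {exc}"
                    )
                s = sensitivities_all_outputs(table, input_name)
                sens_rows.append(
                    {
                        "variant": variant,
                        "input": input_name,
                        "range": str(DEFAULT_RANGES[input_name]),
                        **{f"s_{k}": s[k] for k in OUTPUT_NAMES},
                    }
                )

    files = _dump_partial(stress_rows, kin_rows, sens_rows, out, provenance)
    return {
        "stress_rows": stress_rows,
        "kinematics_rows": kin_rows,
        "sensitivity_rows": sens_rows,
        "files": files,
        "provenance": provenance,
    }


def _dump_partial(stress_rows, kin_rows, sens_rows, out: Path, provenance) -> dict:
    files = {}
    if stress_rows and kin_rows:
        files = write_report(stress_rows, kin_rows, out, metadata=provenance)
    if sens_rows:
        df = pd.DataFrame(sens_rows)
        df.to_csv(out / "sensitivity.csv", index=False)
        files["sensitivity"] = str(out / "sensitivity.csv")
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
    files["provenance"] = str(out / "provenance.json")
    return files
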