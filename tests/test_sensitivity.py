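"""Sensitivity slopes, sweeps, perturbations and convergence bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from sijfem.contact import pressure_overclosure_exponential, pressure_overclosure_linear
from sijfem.fe import SolverSettings
from sijfem.sensitivity import (
    SensitivityError,
    model_outputs,
    scenario_by_name,
    sensitivities_all_outputs,
    sensitivity,
    solve_outputs,
    sweep_parameter,
)


def _table(factors, outputs):
    return pd.DataFrame(
        {"factor": factors, "mean_translation": outputs,
         "mean_stress": outputs, "mean_rotation": outputs}
    )


class TestSensitivitySlope:
    def test_proportional_system_gives_unity(self):
        t = _table([1.0, 2.0], [10.0, 20.0])
        assert np.isclose(sensitivity(t, "load_intensity").sensitivity, 1.0)

    def test_constant_output_gives_zero(self):
        t = _table([0.6, 1.0, 1.4], [3.0, 3.0, 3.0])
        assert sensitivity(t, "x").sensitivity == 0.0

    def test_slope_formula_small_step(self):
        t = _table([1.0, 1.1], [10.0, 11.0])
        assert np.isclose(sensitivity(t, "x").sensitivity, 1.0)

    def test_least_squares_equals_central_difference_on_symmetric_sweep(self):
        f = [0.9, 1.0, 1.1]
        y = [7.3, 8.1, 9.4]
        t = _table(f, y)
        s = sensitivity(t, "x").sensitivity
        central = ((y[2] - y[0]) / y[1]) / (f[2] - f[0])
        assert abs(s - central) < 1e-12

    def test_zero_baseline_rejected(self):
        t = _table([1.0, 1.2], [0.0, 1.0])
        with pytest.raises(SensitivityError, match="zero"):
            sensitivity(t, "x")

    def test_too_few_points_rejected(self):
        with pytest.raises(SensitivityError):
            sensitivity(_table([1.0], [2.0]), "x")

    def test_negative_sensitivity_sign_convention(self):
        # output decreasing with larger input => negative s
        t = _table([0.6, 1.0, 1.4], [4.0, 3.0, 2.0])
        assert sensitivity(t, "x").sensitivity < 0


class TestLinearLimit:
    def test_translation_sensitivity_to_load_is_exactly_one(self):
        # contact off, springs linear and pre-tension off, linearized fiber
        # kinematics: the model is linear, so scaling the load scales the
        # solution exactly and s = 1.  The rigid-fit motion metrics are
        # themselves linear only to first order in u, so the identity is
        # evaluated in the small-response regime (1 % load amplitude).
        mk = {
            "variant": "female_like",
            "seed": 1,
            "pretension_enabled": False,
            "contact_enabled": False,
            "settings": SolverSettings(
                tension_only=False, geometric_nonlinearity=False,
                contact_enabled=False, n_increments=1,
            ),
        }
        case = scenario_by_name("symmetric_xyz").scaled(1e-4)
        table = sweep_parameter("load_intensity", [0.6, 1.0, 1.4],
                                scenario=case, model_kwargs=mk)
        s = sensitivities_all_outputs(table, "load_intensity")
        assert abs(s["mean_translation"] - 1.0) < 1e-6
        assert abs(s["mean_rotation"] - 1.0) < 1e-6
        assert abs(s["mean_stress"] - 1.0) < 1e-6


class TestSweepParameter:
    def test_single_baseline_factor_matches_direct_solve(self, coarse_model):
        case = scenario_by_name("symmetric_xyz")
        direct = solve_outputs(coarse_model, case)
        table = sweep_parameter(
            "load_intensity", [1.0], model_kwargs={"variant": "female_like", "seed": 1}
        )
        for k, v in direct.items():
            assert np.isclose(table.iloc[0][k], v, rtol=1e-9)

    def test_row_counts_match_factors(self):
        mk = {
            "variant": "female_like", "seed": 1,
            "settings": SolverSettings(n_increments=2),
        }
        t = sweep_parameter("load_intensity", [0.6, 1.0, 1.4], model_kwargs=mk)
        assert len(t) == 3
        t2 = sweep_parameter("ligament_reference_length", [0.998, 1.0],
                             model_kwargs=mk)
        assert len(t2) == 2

    def test_unknown_input_rejected(self):
        with pytest.raises(SensitivityError, match="unknown"):
            sweep_parameter("bone_density", [1.0], model_kwargs={})


class TestPerturbationPieces:
    def test_contact_law_pointwise_inequality(self):
        g = np.linspace(0.05, 2.95, 50)
        pe = pressure_overclosure_exponential(g, 3.0, 54.0)
        pl = pressure_overclosure_linear(g, 3.0, 54.0)
        assert np.all(pe < pl)

    def test_zero_attachment_shift_changes_nothing(self):
        from sijfem.modeling import build_model

        a = build_model(variant="female_like", seed=1, attachment_shift=0.0)
        b = build_model(variant="female_like", seed=1)
        assert np.allclose(
            a.mesh.landmarks["gluteal_ground_left"],
            b.mesh.landmarks["gluteal_ground_left"],
        )

    def test_attachment_shift_moves_ground_points_mirrored(self):
        from sijfem.modeling import build_model

        base = build_model(variant="female_like", seed=1)
        shifted = build_model(variant="female_like", seed=1, attachment_shift=-10.0)
        dl = (shifted.mesh.landmarks["gluteal_ground_left"]
              - base.mesh.landmarks["gluteal_ground_left"])
        dr = (shifted.mesh.landmarks["gluteal_ground_right"]
              - base.mesh.landmarks["gluteal_ground_right"])
        assert np.allclose(dl, [-10.0, 0.0, 0.0])
        assert np.allclose(dr, [+10.0, 0.0, 0.0])


class TestPerturbationStudy:
    def test_contact_type_study_solves_and_reports_pct_change(self):
        from sijfem.sensitivity import perturbation_study

        t = perturbation_study(
            "contact_linear_vs_exponential",
            model_kwargs={"variant": "female_like", "seed": 1},
        )
        assert list(t["case"]) == ["baseline", "linear_contact"]
        assert np.allclose(t.iloc[0][["pct_mean_stress", "pct_mean_translation",
                                      "pct_mean_rotation"]], 0.0)
        # swapping to the stiffer (pointwise higher) linear law restrains
        # the joint: less relative motion
        assert t.iloc[1]["pct_mean_translation"] < 0
        assert t.iloc[1]["pct_mean_rotation"] < 0

    def test_friction_study_runs_three_levels(self):
        from sijfem.sensitivity import perturbation_study

        t = perturbation_study(
            "friction_0.2_to_0.6",
            model_kwargs={"variant": "female_like", "seed": 1},
        )
        assert list(t["case"]) == ["baseline", "mu_0.2", "mu_0.6"]
        # more friction => less relative translation
        assert t.iloc[1]["mean_translation"] > t.iloc[0]["mean_translation"]
        assert t.iloc[2]["mean_translation"] < t.iloc[0]["mean_translation"]

    def test_unknown_perturbation_rejected(self):
        from sijfem.sensitivity import perturbation_study

        with pytest.raises(SensitivityError, match="unknown"):
            perturbation_study("gravity_off")


class TestConvergenceStudy:
    def test_three_nested_refinements_converge_toward_finest(self):
        from sijfem.geometry import MorphologyParams
        from sijfem.sensitivity import convergence_study

        df = convergence_study(
            MorphologyParams(variant="female_like", seed=1),
            model_kwargs={"seed": 1},
        )
        assert list(df["level"]) == ["coarse", "medium", "fine"]
        assert df["n_elements"].is_monotonic_increasing
        # differences to the finest level shrink with refinement
        for k in ("reldiff_mean_stress", "reldiff_mean_translation"):
            vals = df[k].to_numpy()
            assert vals[0] >= vals[1] >= vals[2] == 0.0


class TestConvergenceBookkeeping:
    def test_identical_levels_zero_difference(self):
        from sijfem.sensitivity import OUTPUT_NAMES

        rows = pd.DataFrame(
            [
                {"level": "a", "n_elements": 10, "solve_time": 1.0,
                 "mean_stress": 2.0, "mean_translation": 0.5, "mean_rotation": 0.7},
                {"level": "b", "n_elements": 10, "solve_time": 2.0,
                 "mean_stress": 2.0, "mean_translation": 0.5, "mean_rotation": 0.7},
            ]
        )
        ref = rows.iloc[-1]
        for k in OUTPUT_NAMES:
            rel = (rows[k] - ref[k]).abs() / abs(ref[k])
            assert np.allclose(rel, 0.0)

    def test_default_scenario_name(self):
        import inspect

        from sijfem.sensitivity import convergence_study

        sig = inspect.signature(convergence_study)
        assert sig.parameters["scenario"].default == "symmetric_xyz"
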