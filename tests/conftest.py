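"""Shared fixtures.

Expensive artifacts (meshes, solved states) are session-scoped and reused
across test modules.
"""

import numpy as np
import pytest

from sijfem.geometry import MorphologyParams, build_pelvis_mesh
from sijfem.modeling import build_model
from sijfem.fe import solve_quasistatic
from sijfem.sensitivity import scenario_by_name


@pytest.fixture(scope="session")
def coarse_mesh():
    return build_pelvis_mesh(MorphologyParams(variant="female_like", seed=1), "coarse")


@pytest.fixture(scope="session")
def coarse_model():
    return build_model(variant="female_like", seed=1)


@pytest.fixture(scope="session")
def solved_symmetric_xyz(coarse_model):
    case = scenario_by_name("symmetric_xyz")
    return solve_quasistatic(coarse_model, case.side_forces())


@pytest.fixture
def rng():
    return np.random.default_rng(42)
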