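"""Shared fixtures: the fitted response surfaces and the 10 um/h baseline.

The stochastic grid pre-simulation and the baseline coupled integration
are comparatively expensive, so they are session-scoped and shared by
every test that needs them (all are seeded, so results are identical
across runs).
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import neuritesim as ns

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

GRID_SEED = 1


@pytest.fixture(scope="session")
def mt_grid():
    """Raw single-MT grid summaries (default protocol, fixed seed)."""
    return ns.run_grid(ns.GridProtocol(), seed=GRID_SEED)


@pytest.fixture(scope="session")
def surfaces(mt_grid):
    return ns.fit_surfaces(mt_grid)


@pytest.fixture(scope="session")
def baseline_pset(surfaces):
    """Analytically predicted parameter set for 10 um/h outgrowth."""
    spec = ns.SteadyStateSpec(velocity=10.0)
    return ns.predict_parameter_set(spec, surfaces)


@pytest.fixture(scope="session")
def baseline_traj(baseline_pset):
    """5,000 min baseline trajectory with 500 min checkpoints."""
    return ns.integrate(
        baseline_pset.state0, baseline_pset.transport, baseline_pset.mt
    )


def slope(t, y):
    """Least-squares slope helper shared by several tests."""
    return float(np.polyfit(np.asarray(t), np.asarray(y), 1)[0])
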