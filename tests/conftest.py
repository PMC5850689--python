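"""Shared fixtures: baseline parameters and cached steady-state runs.

The steady-state runs at the benchmark concentrations are expensive
(seconds each), so they are computed once per session and shared by
the observable, regime and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from nucleoreplicator import ModelParameters, SolverOptions, integrate_to_steady


@pytest.fixture(scope="session")
def baseline() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def steady_runs(baseline):
    """Settled trajectories at the benchmark joint concentrations."""
    runs = {}
    for rho in (2e-4, 9e-4, 1e-3, 1e-2, 1e-1):
        params = baseline.with_(rho_p=rho, rho_r=rho)
        runs[rho] = integrate_to_steady(params)
    return runs


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_state(system, rng, scale=1e-8):
    """Random nonnegative full state vector with sane pools."""
    y = rng.uniform(0.0, scale, system.dim)
    y[system.i_P1] = rng.uniform(0.0, system.params.rho_p)
    y[system.i_R1] = rng.uniform(0.0, system.params.rho_r)
    return y
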