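"""Shared fixtures: small synthetic trials and one short reference fit."""

import numpy as np
import pytest

import mvgrowth as mg


@pytest.fixture(scope="session")
def uncond_frame():
    """Complete intercepts-only trial at the reference covariance truth."""
    cfg = mg.SimulationConfig(
        n_schools=12,
        children_per_school=(12, 12),
        true_params=mg.TrueParameters.unconditional_reference(),
        missingness=mg.MissingnessSpec.none(),
        seed=11,
    )
    frame, truth = mg.simulate_trial(cfg)
    return frame, truth


@pytest.fixture(scope="session")
def full_frame():
    """Small full-model trial with cell-level MAR missingness."""
    cfg = mg.SimulationConfig(
        n_schools=20,
        children_per_school=(10, 10),
        missingness=mg.MissingnessSpec(cell_level=True),
        seed=12,
    )
    frame, truth = mg.simulate_trial(cfg)
    return frame, truth


@pytest.fixture(scope="session")
def full_samples(full_frame):
    """Short full-model fit reused by posterior and reporting tests."""
    frame, _ = full_frame
    return mg.fit_model(
        frame, mg.ModelSpec.full(), n_chains=2, n_iter=500, burn_in=150, seed=13
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
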