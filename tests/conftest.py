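"""Shared fixtures: small synthetic datasets and a fitted S/T model.

Everything is generated programmatically at fixed seeds; the heavier
fixtures are session-scoped so the predictor is trained once.
"""

from __future__ import annotations

import numpy as np
import pytest

from phoskit.predictor import PhosphositeModel
from phoskit.simulate import OrthoSimConfig, SimulationConfig, simulate_proteome


@pytest.fixture(scope="session")
def small_proteome():
    """60 synthetic proteins with planted S/T/Y sites and true disorder."""
    return simulate_proteome(SimulationConfig(seed=11, n_proteins=60))


@pytest.fixture(scope="session")
def heldout_proteome():
    """Independent draw from the same world, for held-out evaluation."""
    return simulate_proteome(SimulationConfig(seed=12, n_proteins=40))


@pytest.fixture(scope="session")
def fitted_st_model(small_proteome):
    """Bootstrap-balanced S/T ensemble fitted on the small proteome."""
    records, profiles = small_proteome
    model = PhosphositeModel.from_records(records, "ST", profiles=profiles,
                                          seed=3)
    return model.fit(B=10, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
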