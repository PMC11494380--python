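"""Shared fixtures: simulated datasets and trained models.

The heavyweight fixtures are session-scoped so the full-scale training runs
once and is reused by every test that needs a well-trained model.
"""

from __future__ import annotations

import numpy as np
import pytest

from lineagevae import LineageVAE, ModelConfig, SimConfig, simulate, train

# training budget used throughout the study-scale tests (package defaults
# stay at 200/200; the longer dynamics phase matches the published schedule)
STUDY_EPOCHS = dict(epochs_phase1=200, epochs_phase2=1000)


@pytest.fixture(scope="session")
def default_sim():
    """The default desk-scale clonal simulation (10 lineages x 25 cells)."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def trained_model(default_sim):
    """Model trained at study scale on the default simulation."""
    ds, _ = default_sim
    model, history = train(ds, ModelConfig(seed=1, **STUDY_EPOCHS))
    return model, history


@pytest.fixture(scope="session")
def tiny_sim():
    """A very small simulation for fast unit tests."""
    cfg = SimConfig(n_lineages=4, cells_per_lineage=10, n_genes=60,
                    latent_dim=4, seed=7)
    return simulate(cfg)


@pytest.fixture(scope="session")
def tiny_model(tiny_sim):
    """A briefly trained model — enough to exercise inference code paths."""
    ds, _ = tiny_sim
    cfg = ModelConfig(latent_dim=5, epochs_phase1=20, epochs_phase2=30, seed=7)
    model, _ = train(ds, cfg)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
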