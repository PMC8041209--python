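"""Shared fixtures: one synthetic study panel and its fitted models.

Session-scoped so that the expensive objects (panel generation, the two
model fits) are built once and reused across test modules.
"""

import numpy as np
import pandas as pd
import pytest

from equicare import (
    GlucoseTransitionModel,
    ZeroInflatedPoissonModel,
    generate_panel,
    generate_zip_table,
    prepare_panel,
    recovery_ground_truth,
    simulate_transition_observations,
)


@pytest.fixture(scope="session")
def zips():
    return generate_zip_table(95, seed=11)


@pytest.fixture(scope="session")
def truth():
    return recovery_ground_truth(seed=11)


@pytest.fixture(scope="session")
def panel(zips, truth):
    return generate_panel(800, 6, zips, truth)


@pytest.fixture(scope="session")
def prepared(panel, zips):
    lagged, transitions, report = prepare_panel(panel, zips)
    # model recovery tests condition on the generative severity class
    lagged = lagged.assign(clinical_cluster=lagged["severity_class"])
    return lagged, transitions, report


@pytest.fixture(scope="session")
def zip_fit(prepared):
    lagged, _, _ = prepared
    return ZeroInflatedPoissonModel.from_panel(lagged, "phys_encounters").fit()


@pytest.fixture(scope="session")
def transition_obs(truth):
    return simulate_transition_observations(truth.transition_params, 6000,
                                            seed=3)


@pytest.fixture(scope="session")
def transition_fit(transition_obs):
    return GlucoseTransitionModel.from_transitions(transition_obs).fit()
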