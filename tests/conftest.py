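import numpy as np
import pandas as pd
import pytest

from metastair.simulate import (
    ExperimentConfig,
    ObserverParams,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 12-subject simulated experiment shared across tests (seeded)."""
    return simulate_experiment(ExperimentConfig(n_subjects=12, seed=42))


@pytest.fixture(scope="session")
def clean_cohort() -> pd.DataFrame:
    """A cohort with no RT contamination and no sub-4-item trials possible
    (high capacity floor via zero lapse and moderate capacities), so only
    practice/burn-in exclusions apply."""
    obs = ObserverParams(
        rt_params=__import__("metastair.simulate", fromlist=["RTParams"]).RTParams(
            p_fast=0.0, p_timeout_decision=0.0, p_timeout_confidence=0.0
        ),
        capacity_im=6.0,
        capacity_wm=6.0,
        capacity_sd=0.0,
        capacity_within_sd=0.0,
    )
    return simulate_experiment(ExperimentConfig(n_subjects=4, seed=7, observer=obs))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
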