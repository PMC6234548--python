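"""Shared fixtures: hand-built toy cohorts and small simulated datasets."""

import numpy as np
import pandas as pd
import pytest

from mstforest.data import MultistateDataset, TransitionStructure
from mstforest.simulate import (
    Baseline,
    Censoring,
    CovariateSpec,
    SimulationScenario,
    hivlike_scenario,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def illness_death():
    return TransitionStructure.illness_death()


@pytest.fixture(scope="session")
def toy_dataset(illness_death):
    """Four-subject illness-death cohort.

    A: 1->2 at 2, 2->3 at 5; B: 1->2 at 1, censored in 2 at 6;
    C: 1->3 at 3; D: censored in 1 at 4.
    """
    table = pd.DataFrame(
        [
            ("A", 1, 2, 0.0, 2.0, 1, 0.1),
            ("A", 2, 3, 2.0, 5.0, 1, 0.1),
            ("B", 1, 2, 0.0, 1.0, 1, 0.9),
            ("B", 2, 0, 1.0, 6.0, 0, 0.9),
            ("C", 1, 3, 0.0, 3.0, 1, 0.5),
            ("D", 1, 0, 0.0, 4.0, 0, 0.3),
        ],
        columns=["id", "from", "to", "entry", "exit", "status", "x"],
    )
    return MultistateDataset(table, illness_death)


@pytest.fixture(scope="session")
def two_state_scenario():
    """Two-state 1 -> 2 scenario with constant rate 0.2 and no covariates."""
    return SimulationScenario(
        TransitionStructure.progressive(2),
        2000,
        {(1, 2): Baseline("exponential", rate=0.2)},
        name="two-state",
    )


@pytest.fixture(scope="session")
def markov_idm_scenario():
    """Markov illness-death scenario with constant rates and no covariates."""
    return SimulationScenario(
        TransitionStructure.illness_death(),
        2000,
        {
            (1, 2): Baseline("exponential", rate=0.2),
            (1, 3): Baseline("exponential", rate=0.1),
            (2, 3): Baseline("exponential", rate=0.3),
        },
        name="markov-idm",
    )


@pytest.fixture(scope="session")
def small_cohort():
    """hivlike cohort at n=300 with moderate censoring, cached per session."""
    ds, truth = simulate_cohort(hivlike_scenario(300), seed=42)
    return ds, truth


@pytest.fixture(scope="session")
def covariate_effect_scenario():
    """Two-state scenario with one strong binary covariate doubling the rate."""
    return SimulationScenario(
        TransitionStructure.progressive(2),
        300,
        {(1, 2): Baseline("exponential", rate=0.15)},
        betas={(1, 2): {"z": np.log(2.0)}},
        covariates=(CovariateSpec("z", "binary", p=0.5),),
        censoring=Censoring(rate=0.05, admin_tau=15.0),
        name="one-covariate",
    )
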