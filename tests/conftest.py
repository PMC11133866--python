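import numpy as np
import pandas as pd
import pytest

from emgreact import SimulationConfig, StudyDesign, simulate_binned
from emgreact.preprocess import (
    aggregate_cells,
    baseline_bin_table,
    trial_percent_change_table,
)

FULL_SEED = 20240515


@pytest.fixture(scope="session")
def full_table() -> pd.DataFrame:
    """Full-size default simulation (156 participants, 15 trials)."""
    return simulate_binned(SimulationConfig(seed=FULL_SEED))


@pytest.fixture(scope="session")
def full_trial_scores(full_table) -> pd.DataFrame:
    return trial_percent_change_table(full_table)


@pytest.fixture(scope="session")
def full_cells(full_trial_scores) -> pd.DataFrame:
    return aggregate_cells(full_trial_scores)


@pytest.fixture(scope="session")
def full_baseline_bins(full_table) -> pd.DataFrame:
    return baseline_bin_table(full_table)


@pytest.fixture()
def small_config() -> SimulationConfig:
    design = StudyDesign(n_participants=8, n_trials_per_condition=4)
    return SimulationConfig(design=design, seed=11)


@pytest.fixture()
def small_table(small_config) -> pd.DataFrame:
    return simulate_binned(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
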