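import numpy as np
import pandas as pd
import pytest

from placebo_rl.cohort import GroupTruth, simulate_study
from placebo_rl.task import TaskConfig


@pytest.fixture(scope="session")
def config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def default_truth() -> GroupTruth:
    return GroupTruth()


@pytest.fixture(scope="session")
def small_study(default_truth) -> pd.DataFrame:
    """A compact but complete 6-subject, 3-condition study."""
    return simulate_study(default_truth, n_subjects=6, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
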