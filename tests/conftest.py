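import numpy as np
import pandas as pd
import pytest

from bpvar import (AnalysisDataset, LongitudinalData, SimConfig, SurvivalData,
                   simulate_dataset)


@pytest.fixture
def toy_longitudinal() -> LongitudinalData:
    """Three subjects, three visits each, hand-enterable values."""
    df = pd.DataFrame({
        "id": [1, 1, 1, 2, 2, 2, 3, 3, 3],
        "time": [0.0, 3.0, 6.0] * 3,
        "value": [100.0, 100.0, 100.0, 110.0, 120.0, 130.0, 95.0, 105.0, 91.0],
    })
    return LongitudinalData(df)


@pytest.fixture
def toy_dataset(toy_longitudinal) -> AnalysisDataset:
    surv = SurvivalData(pd.DataFrame({
        "id": [1, 2, 3], "time": [5.0, 15.0, 20.0], "status": [1, 1, 0]}))
    return AnalysisDataset(toy_longitudinal, surv)


@pytest.fixture(scope="session")
def scenario1_dataset():
    """One default Scenario-1 cohort (N=1500, 4 visits) plus latent truth."""
    return simulate_dataset(SimConfig(scenario=1, seed=20240501))


@pytest.fixture(scope="session")
def scenario2_dataset():
    """One default Scenario-2 cohort (event-truncated measurement streams)."""
    return simulate_dataset(SimConfig(scenario=2, seed=20240502))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
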