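import numpy as np
import pytest

import gaitbalance as gb
from gaitbalance.imuprep import ChannelScaler
from gaitbalance.train import split_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic cohort shared across tests."""
    spec = gb.CohortSpec(n_old=4, n_young=4, trials_per_subject=4, seed=42)
    return gb.make_cohort(spec)


@pytest.fixture(scope="session")
def split_and_scaler(small_cohort):
    tr, va, te = split_dataset(small_cohort.trials, seed=0)
    scaler = ChannelScaler.fit(tr)
    return tr, va, te, scaler


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
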