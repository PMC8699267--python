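import numpy as np
import pandas as pd
import pytest

from wimt import SimParams, simulate_dilution_series


def make_feature_frame(rows):
    return pd.DataFrame(
        rows, columns=["run_id", "feature_id", "mz", "rt_min", "charge", "intensity", "snr"]
    )


@pytest.fixture(scope="session")
def small_dilution():
    """One shared small dilution simulation (100 proteins, seed 7)."""
    return simulate_dilution_series(SimParams(n_proteins=100, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
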