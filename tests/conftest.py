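import numpy as np
import pytest

from gammafht import SurvivalDataset, generate_example1


@pytest.fixture(scope="session")
def example1_small():
    """A 300-row strong-signal dataset shared across tests."""
    return generate_example1(300, seed=11)


@pytest.fixture
def toy_dataset():
    """Six observations, two censored, one covariate."""
    times = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
    status = np.array([1, 0, 1, 1, 0, 1])
    X = np.column_stack([np.ones(6), np.array([0.1, 0.9, 0.4, 0.6, 0.2, 0.8])])
    return SurvivalDataset(times=times, status=status, X=X, columns=["x1"])
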