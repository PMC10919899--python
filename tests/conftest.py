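import numpy as np
import pytest

from vorloop.fitting import RegularizationSpec, sweep_feedback
from vorloop.synth import build_fit_dataset

DT = 5e-4


@pytest.fixture(scope="session")
def dataset_noiseless():
    """Noiseless synthetic dataset generated from the weak-feedback truth."""
    return build_fit_dataset(noiseless=True)


@pytest.fixture(scope="session")
def dataset_noisy():
    """Default noisy trial-averaged dataset (small, for fast tests)."""
    return build_fit_dataset(n_cells=3, n_trials=4, seed=7)


@pytest.fixture(scope="session")
def sweep11(dataset_noiseless):
    """Warm 11-point feedback-gain sweep (increase learning), shared across
    the acceptance checks that analyze it."""
    return sweep_feedback(dataset_noiseless,
                          g_values=np.round(np.arange(0, 1.01, 0.1), 10),
                          reg=RegularizationSpec(),
                          directions=("increase",), maxiter=60)


@pytest.fixture(scope="session")
def fit_g0(sweep11):
    """The fitted model at g = 0 (No Feedback), reused by several checks."""
    return sweep11[0]
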