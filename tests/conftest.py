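import warnings

import numpy as np
import pandas as pd
import pytest

import emosearch as es
from emosearch.mcmc import FitConfig

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def light_fit_config():
    """Reduced MCMC budget for unit tests that exercise the fitting path
    without asserting convergence diagnostics."""
    return FitConfig(n_iter=900, n_warmup=400, theta_refresh=1)


@pytest.fixture(scope="session")
def one_group_config():
    """Single-group generator at first-grade truths, desk-scale size."""
    return es.SimulationConfig(
        n_participants_per_group=15,
        n_trials_per_participant=96,
        group_labels=("I",),
        exgauss_truth={k: v for k, v in es.DEFAULT_EXGAUSS_TRUTH.items() if k[0] == "I"},
        sdt_truth={k: v for k, v in es.DEFAULT_SDT_TRUTH.items() if k[0] == "I"},
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def small_trials(one_group_config) -> pd.DataFrame:
    return es.generate_behavioral_dataset(one_group_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
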