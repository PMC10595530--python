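import warnings

import numpy as np
import pytest

from ewstme.preprocess import normalize
from ewstme.synthetic import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Mid-size default-structure cohort shared across read-only tests."""
    cfg = SimConfig(seed=11, n_samples=6, n_patients=4, cells_per_sample=(150, 180), n_genes=1200)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def norm(cohort):
    counts, _, _, _ = cohort
    return normalize(counts)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Domain warnings (dropped genes, shrunk windows) are expected in tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(0)
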