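import numpy as np
import pandas as pd
import pytest

from immunexpo.synthetic import ChainSpec, SyntheticConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """300-sample cohort with blocks, covariate/batch/season effects and two
    planted chains; reused across read-only tests."""
    cfg = SyntheticConfig(
        n_samples=300, n_exposures=12, exposure_block_sizes=(4, 4),
        within_block_r=0.6, n_phenotypes=10, n_omics=30,
        covariate_effects={"age": 0.3, "gender": 0.4},
        seasonal_amplitude=0.5, seasonal_phase=3.0,
        batch_count=5, batch_sd=0.5,
        mediation_chains=(
            ChainSpec("D1", "EXP009", "OMX0001", "IP001", 0.5, 0.4, 0.1),
            ChainSpec("D2", "EXP010", "IP002", "OMX0002", 0.5, 0.4, 0.1),
        ),
        missing_rate=0.02, skew_fraction=0.3, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted effects at all."""
    cfg = SyntheticConfig(n_samples=300, n_exposures=20, n_phenotypes=25,
                          n_omics=10, seed=99)
    return generate_cohort(cfg)


def ols_slope(x, y):
    """Independent simple-regression oracle used by several tests."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    return float(np.dot(xc, y) / np.dot(xc, xc))


@pytest.fixture
def frame_of(rng):
    def make(arr):
        arr = np.asarray(arr, float)
        return pd.DataFrame(arr, index=[f"S{i}" for i in range(arr.shape[0])])
    return make
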