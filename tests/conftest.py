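import numpy as np
import pandas as pd
import pytest

from featclust import (
    GaussianSimConfig,
    NBSimConfig,
    simulate_gaussian_two_group,
    simulate_nb_counts,
)


@pytest.fixture(scope="session")
def fixture_matrix() -> pd.DataFrame:
    """Fixed 6-gene x 10-sample matrix mixing unimodal and bimodal genes."""
    rng = np.random.default_rng(20210224)
    rows = [
        rng.normal(5.0, 1.0, 10),                       # unimodal
        rng.normal(0.0, 2.0, 10),                       # wide unimodal
        np.concatenate([rng.normal(-3, 0.4, 5), rng.normal(3, 0.4, 5)]),
        np.concatenate([rng.normal(0, 0.3, 7), rng.normal(6, 0.3, 3)]),
        rng.lognormal(1.0, 0.6, 10),                    # skewed
        rng.normal(2.0, 0.1, 10),                       # tight
    ]
    return pd.DataFrame(
        np.array(rows),
        index=[f"g{i}" for i in range(1, 7)],
        columns=[f"s{j}" for j in range(1, 11)],
    )


@pytest.fixture(scope="session")
def small_gaussian():
    """Scaled-down Gaussian two-group dataset (1,000 x 60)."""
    cfg = GaussianSimConfig(
        n_per_group=30, n_features=1000, n_informative=50,
        effect_size=1.0, seed=11,
    )
    return simulate_gaussian_two_group(cfg)


@pytest.fixture(scope="session")
def small_nb():
    """Small NB count dataset with 10% DE genes."""
    cfg = NBSimConfig(
        n_samples_a=25, n_samples_b=25, n_genes=400,
        frac_de=0.1, log2_fc=2.0, seed=5,
    )
    return simulate_nb_counts(cfg)
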