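import numpy as np
import pandas as pd
import pytest

from prostaxis.synthetic_cohort import SimConfig, generate_expression


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Five cohorts of 40 samples, 600 genes: fast but structurally complete."""
    return SimConfig(samples_per_cohort=40, n_genes=600, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """(expression, meta, true activities) for the small configuration."""
    return generate_expression(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_expression() -> pd.DataFrame:
    """4 genes x 3 samples with known orderings and one tie."""
    return pd.DataFrame(
        {
            "s1": [5.0, 1.0, 3.0, 9.0],
            "s2": [2.0, 2.0, 7.0, 1.0],
            "s3": [4.0, 4.0, 4.0, 4.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
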