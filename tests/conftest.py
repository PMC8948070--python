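import numpy as np
import pandas as pd
import pytest

from lianameta.simulate import SimConfig, agb_config, generate_meta_dataset


@pytest.fixture(scope="session")
def growth_table() -> pd.DataFrame:
    """Default synthetic growth-arm study table (26 studies, 103 rows)."""
    return generate_meta_dataset(SimConfig(seed=5))


@pytest.fixture(scope="session")
def growth_table_complete() -> pd.DataFrame:
    """Growth-arm table with no missing SDs (all variances computable)."""
    return generate_meta_dataset(SimConfig(seed=5, missing_variance_fraction=0.0))


@pytest.fixture(scope="session")
def agb_table() -> pd.DataFrame:
    """Default synthetic biomass-arm table (12 studies, 69 rows)."""
    return generate_meta_dataset(agb_config(seed=7))


@pytest.fixture()
def small_effects() -> pd.DataFrame:
    """Six effects from six studies with observed variances."""
    rng = np.random.default_rng(11)
    k = 6
    return pd.DataFrame({
        "study_id": [f"s{i}" for i in range(k)],
        "comparison_id": ["c1"] * k,
        "measure": ["smd"] * k,
        "estimate": rng.normal(0.8, 0.4, k),
        "variance": rng.uniform(0.05, 0.4, k),
        "variance_was_imputed": [False] * k,
        "n_t": rng.integers(4, 10, k),
        "n_c": rng.integers(4, 10, k),
    })
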