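import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from icemoor import CommunityMatrix, synthetic

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def env_miz() -> pd.DataFrame:
    """Two years of weekly MIZ sampling."""
    return synthetic.generate_env_series(
        n_years=2, site="MIZ", sampling_interval_days=7, seed=11
    )


@pytest.fixture(scope="session")
def env_core() -> pd.DataFrame:
    return synthetic.generate_env_series(
        n_years=2, site="core-EGC", sampling_interval_days=14, seed=11
    )


@pytest.fixture(scope="session")
def small_community(env_miz):
    """Modest planted community shared across read-only tests."""
    return synthetic.generate_community(
        env_miz,
        n_resident=30,
        n_intermittent=60,
        n_transient=60,
        depth_per_sample=20_000,
        seed=5,
    )


@pytest.fixture(scope="session")
def lineage_pool():
    return synthetic.make_lineage_pool()


@pytest.fixture()
def toy_matrix() -> CommunityMatrix:
    counts = pd.DataFrame(
        {
            "s1": [5, 1, 0, 2],
            "s2": [4, 0, 1, 2],
            "s3": [6, 0, 0, 2],
        },
        index=pd.Index(["a", "b", "c", "d"], name="asv_id"),
    )
    return CommunityMatrix(counts)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
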