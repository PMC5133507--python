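import numpy as np
import pytest

from srvs.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but non-trivial cohort shared across tests (read-only)."""
    cfg = SyntheticConfig(n_subjects=80, n_snps=120, n_expr=40, n_families=10,
                          n_causal_snps=3, n_causal_expr=2, n_eqtl_links=5, seed=7)
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
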