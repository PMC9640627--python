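import numpy as np
import pytest

from lncpath import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort with planted signal, shared across read-only tests."""
    cfg = SyntheticConfig(n_samples=120, n_mrna=120, n_lncrna=20,
                          pathway_set_size=15, n_active_lnc=3, seed=42)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
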