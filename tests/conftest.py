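import numpy as np
import pytest

from tumorfidelity import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Four-patient cohort at reduced size for fast structural tests."""
    cfg = CohortConfig(seed=7, n_somatic_sites=60, n_germline_sites=200,
                       n_reads=4000, probes_per_chrom=40)
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
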