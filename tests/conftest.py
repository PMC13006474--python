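import numpy as np
import pytest

from rcnvclock.rcnv_detection import RCNVLocus
from rcnvclock.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest noiseless-genotyping cohort shared by read-only tests."""
    config = SimulationConfig(
        seed=11, n_samples=60, n_carriers=30, tau_true=100.0, genotyping_error=0.0
    )
    haps, gmap, truth, pheno = simulate_cohort(config)
    return config, haps, gmap, truth, pheno


@pytest.fixture(scope="session")
def cohort_locus(small_cohort):
    config, _, _, truth, _ = small_cohort
    start, end = config.cnv_interval
    return RCNVLocus(
        locus_id="L0001",
        chrom=config.chrom,
        start=start,
        end=end,
        state=truth.cnv_state,
        carriers=frozenset(truth.carrier_ids),
        carrier_frequency=len(truth.carrier_ids) / config.n_samples,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
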