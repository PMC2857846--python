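import numpy as np
import pytest

from growsel import McmcConfig, SimConfig, run_two_step, simulate_dataset


@pytest.fixture(scope="session")
def default_runs():
    """Full-size datasets and pipeline runs (desk-scale chains) for 3 seeds."""
    out = {}
    for seed in (1, 2, 3):
        ds = simulate_dataset(seed=seed)
        out[seed] = (ds, run_two_step(ds, mcmc=McmcConfig.desk_scale(seed=seed)))
    return out


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Scaled-down study design for fast end-to-end tests."""
    return SimConfig(
        n_families=20,
        n_offspring=10,
        n_snp=60,
        n_chrom=2,
        n_qtl_asym=3,
        n_qtl_xmid=2,
        n_qtl_scal=2,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
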