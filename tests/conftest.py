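import numpy as np
import pytest

from clonemut.presets import preset_sim_config
from clonemut.simulate import simulate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 100-kb, 3-clone mock cohort shared by read-only tests."""
    cfg = preset_sim_config(
        "mock", genome_length=100_000, chrom_count=2, n_clones=3,
        germline_het_count=60, n_snv=40, n_ins=4, n_del=4, seed=7,
    )
    reference, truth, pileup = simulate_cohort(cfg)
    return cfg, reference, truth, pileup
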