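import numpy as np
import pytest

from kmersig.simulate import (
    SimConfig,
    make_reference,
    plant_events,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        genome_length=200_000,
        n_genes=40,
        n_events=6,
        n_per_group=(4, 6),
        seed=1,
        gene_mean=6,
    )


@pytest.fixture(scope="session")
def small_reference(small_cfg):
    return make_reference(small_cfg)


@pytest.fixture(scope="session")
def small_truth(small_cfg, small_reference):
    return plant_events(small_reference, small_cfg)


@pytest.fixture(scope="session")
def small_cohort(small_cfg, small_reference, small_truth):
    return simulate_reads(small_truth, small_reference, small_cfg)


@pytest.fixture(scope="session")
def small_sam_dir(tmp_path_factory, small_cohort):
    d = tmp_path_factory.mktemp("sam")
    return small_cohort.write_sam(str(d))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
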