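import numpy as np
import pytest

from apfam.synthetic import SimulationConfig, simulate_family_genome

SMALL_CONFIG = SimulationConfig(
    seed=11,
    n_chromosomes=4,
    chromosome_length_bp=900_000,
    n_family_genes=12,
    category_mix=(2, 2, 8),
    tandem_cluster_sizes=(3,),
    segmental_pairs=((12, 2), (20, 3)),
    n_xylem_specific=3,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A 12-gene synthetic genome (2/2/8 category mix) shared across tests."""
    return simulate_family_genome(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_dataset_dir(small_dataset, tmp_path_factory):
    d = tmp_path_factory.mktemp("synthetic")
    small_dataset.write(d)
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
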