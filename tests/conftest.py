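import pytest

from chromaquant import SimulationConfig, simulate_annotation, simulate_expression


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(seed=11, n_genes=40, chrom_length=800_000)


@pytest.fixture(scope="session")
def small_annotation(small_cfg):
    return simulate_annotation(small_cfg)


@pytest.fixture(scope="session")
def small_genes(small_annotation):
    return small_annotation[0]


@pytest.fixture(scope="session")
def small_chrom_sizes(small_annotation):
    return small_annotation[1]


@pytest.fixture(scope="session")
def small_expression(small_genes, small_cfg):
    return simulate_expression(small_genes, small_cfg)
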