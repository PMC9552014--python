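import pytest

import mvifmda as mv
from mvifmda.io import prepare_views

#: compact planted dataset for fast model/training tests
SMALL_CONFIG = mv.SynthConfig(
    n_mirna=40, n_disease=16, n_clusters=4, n_genes=120,
    genes_per_entity=(4, 8), seed=7,
)


@pytest.fixture(scope="session")
def tiny_dataset():
    return mv.tiny_fixture()


@pytest.fixture(scope="session")
def tiny_views(tiny_dataset):
    return prepare_views(tiny_dataset)


@pytest.fixture(scope="session")
def small_dataset():
    return mv.simulate(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_views(small_dataset):
    return prepare_views(small_dataset)


@pytest.fixture
def fast_config():
    """Model config small enough for second-scale training runs."""
    return mv.ModelConfig(n_layers=2, f_topology=16, f_channel=16,
                          epochs=15, seed=3)
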