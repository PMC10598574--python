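import numpy as np
import pytest

from synergraph.config import GenConfig, RunConfig
from synergraph.synthgen import generate

TINY = dict(n_drugs=20, n_proteins=50, n_cells=10, n_genes=120, n_records=300,
            seed=21)


@pytest.fixture(scope="session")
def tiny_data(tmp_path_factory):
    """Small generated dataset shared by the model/evaluation tests."""
    outdir = tmp_path_factory.mktemp("tiny")
    return generate(GenConfig(**TINY), outdir)


@pytest.fixture(scope="session")
def tiny_config():
    cfg = RunConfig(seed=21)
    cfg.featurize.cell_n_genes = TINY["n_genes"]
    cfg.train.epochs = 30
    cfg.train.patience = 30
    return cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
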