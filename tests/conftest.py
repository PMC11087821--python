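import numpy as np
import pytest

import draphnet as dn


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-model data set shared by read-only tests."""
    config = dn.SimConfig(
        n_drugs=60, n_endpoints=80, n_genes=150, n_phenotypes=20, seed=11
    )
    return dn.generate(config)


@pytest.fixture(scope="session")
def small_model(small_sim):
    """A fitted model on the small data set (weak penalty)."""
    D, G, Y, _, _ = small_sim
    dec = dn.soft_impute(D, rank=4, lam=0.0)
    gd = dn.decompose_gene_matrix(G, 4)
    config = dn.ModelConfig(r_D=4, r_P=4, l1_strength=1e-3, seed=0)
    return dn.fit(dn.drug_factors(dec), gd, Y, config, gene_ids=G.gene_ids)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
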