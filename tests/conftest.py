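import numpy as np
import pytest

import tdfe


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tensor(rng, shape=(4, 3, 3, 2)):
    return rng.normal(size=shape)


@pytest.fixture(scope="session")
def default_run():
    """One end-to-end run of the standard benchmark simulation (seed 0)."""
    cfg = tdfe.SimulationConfig(seed=0)
    matrices, sample_map, truth = tdfe.generate_dataset(cfg)
    genes = tdfe.intersect_genes(matrices)
    tensor = tdfe.build_tensor(matrices, sample_map, genes)
    factors = tdfe.hosvd(tensor)
    choice = tdfe.select_components(factors)
    table = tdfe.score_genes(factors.gene_factor, choice.gene_components, genes)
    return {
        "config": cfg,
        "matrices": matrices,
        "sample_map": sample_map,
        "truth": truth,
        "tensor": tensor,
        "factors": factors,
        "choice": choice,
        "table": table,
    }
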