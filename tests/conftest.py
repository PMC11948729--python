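import numpy as np
import pytest

import blocklasso as bl


@pytest.fixture(scope="session")
def small_sim():
    """4 blocks x 50 SNVs x 400 samples with 10 causal SNVs, a=2."""
    cfg = bl.SimConfig(
        n_samples=400, n_blocks=4, n_features_per_block=50,
        n_causal=10, error_scale=2.0, seed=7,
    )
    genotypes = bl.simulate_genotype_blocks(cfg)
    phenotype, truth = bl.simulate_phenotype(genotypes, 10, 2.0, seed=8)
    return cfg, genotypes, phenotype, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
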