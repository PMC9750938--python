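import numpy as np
import pytest

from burdenmr import simcohort as sc


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort shared by io/annotate/burden tests (600 x 30 genes)."""
    cfg = sc.CohortConfig(
        n_samples=600,
        n_genes=30,
        seed=7,
        causal_genes=(sc.CausalGene("GENE0004", "HC_PTV", 1.6, carrier_freq=0.05),),
    )
    variants, gtab, annotations, covariates = sc.simulate_cohort(cfg)
    return cfg, variants, gtab, annotations, covariates


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
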