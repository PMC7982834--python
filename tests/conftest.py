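import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bmmscan import SimConfig, simulate_cohort

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-sample, 600-SNP, two-chromosome cohort with default conditions."""
    cfg = SimConfig(n_samples=60, n_snps=600, n_chroms=2, seed=1)
    panel, genotypes, covariates, truth, genes, lists, snp_class = simulate_cohort(cfg)
    return {
        "config": cfg, "panel": panel, "genotypes": genotypes,
        "covariates": covariates, "truth": truth, "genes": genes,
        "lists": lists, "snp_class": snp_class,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
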