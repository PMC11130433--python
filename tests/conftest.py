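import numpy as np
import pytest

from tempoqtl.simulate import SimConfig, simulate_genotypes
from tempoqtl.statgen import maf_filter_impute


@pytest.fixture(scope="session")
def small_geno():
    """Structured inbred genotypes: 60 accessions x 200 markers, 3 subpops."""
    cfg = SimConfig(
        n_accessions=60, n_subpops=3, fst=0.15, n_markers=200, n_chromosomes=3,
        seed=7,
    )
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def filtered_geno(small_geno):
    return maf_filter_impute(small_geno)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
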