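import numpy as np
import pytest

from photoacclim import (
    compute_kinship,
    default_schedule,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_panel():
    """60 accessions x 300 SNPs with mild structure, plus kinship."""
    G = simulate_genotypes(60, 300, n_subpops=2, fst=0.1, seed=42)
    K = compute_kinship(G)
    lam, U = np.linalg.eigh(K.values)
    return G, K, (lam, U)


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def small_pheno(small_panel, schedule):
    G, K, _ = small_panel
    return simulate_phenotypes(
        G, K, schedule, h2_ll=0.05, h2_hl=0.4, n_replicates=3, seed=7
    )
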