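import warnings

import numpy as np
import pytest

from bambuseq.synthetic import SimConfig, simulate_gene_models

warnings.filterwarnings("ignore", message=".*gap placed only.*")


@pytest.fixture(scope="session")
def small_genes():
    """A handful of simulated multi-exon genes shared across tests."""
    return simulate_gene_models(SimConfig(seed=101, n_genes=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
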