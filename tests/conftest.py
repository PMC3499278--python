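import numpy as np
import pytest

from ormine.pipeline import analyze
from ormine.synthetic import plant_genome


@pytest.fixture(scope="session")
def bench():
    """Benchmark synthetic genome at the standard study conditions
    (100 genes, 15% pseudo, 10% partial, 2% aa mutation, 5 duplicate pairs
    + 1 triplet) together with the full analysis result."""
    syn = plant_genome(rng_seed=0)
    res = analyze(syn.genome, syn.references)
    return syn, res


@pytest.fixture(scope="session")
def small_syn():
    """Small duplication-free synthetic genome for fast per-module tests."""
    return plant_genome(n_genes=12, dup_spec=None, n_contigs=2, rng_seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
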