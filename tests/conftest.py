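import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from retrodup.synthetic_data import simulate_genome_with_genes


@pytest.fixture(scope="session")
def small_gene_bundle():
    """A reusable small genome with multi-exon genes (seeded)."""
    genome, models, proteins = simulate_genome_with_genes(
        12, (3, 6), 200_000, seed=42)
    return genome, models, proteins


@pytest.fixture(scope="session")
def tiny_gene_bundle():
    """Short-protein genes sized for the pure-Python DP oracle."""
    genome, models, proteins = simulate_genome_with_genes(
        10, (3, 5), 120_000, seed=7, protein_length_range=(60, 90),
        intron_length_range=(60, 150))
    return genome, models, proteins


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
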