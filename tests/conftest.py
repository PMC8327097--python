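import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from ovisweep.genotype_io import GenotypeDataset
from ovisweep.synthetic_data import SimConfig, simulate_divergent_pops


@pytest.fixture
def two_pop_sim():
    """Small two-population mosaic simulation with LD (deterministic)."""
    cfg = SimConfig(n_per_pop=30, n_variants=400, chrom_length_bp=8_000_000,
                    target_fst=0.05, rng_seed=11)
    return simulate_divergent_pops(cfg)


@pytest.fixture
def unlinked_sim():
    """Unlinked-site simulation (no LD), for null-expectation checks."""
    cfg = SimConfig(n_per_pop=100, n_variants=2000, chrom_length_bp=50_000_000,
                    target_fst=0.0, founders_per_pop=None, rng_seed=7)
    return simulate_divergent_pops(cfg)


def make_dataset(genotype, pos=None, chrom=None, labels=None):
    """Build a GenotypeDataset from a raw genotype matrix with defaults."""
    genotype = np.asarray(genotype, dtype=np.int8)
    n, m = genotype.shape
    pos = np.arange(1, m + 1) * 10_000 if pos is None else np.asarray(pos)
    chrom = ["1"] * m if chrom is None else chrom
    labels = ["P1"] * n if labels is None else labels
    return GenotypeDataset(
        sample_ids=[f"s{i}" for i in range(n)],
        population_labels=list(labels),
        variant_ids=[f"v{j}" for j in range(m)],
        chrom=np.asarray(chrom, dtype=object),
        pos_bp=pos,
        genotype=genotype,
    )
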