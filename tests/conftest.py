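import numpy as np
import pytest

import invscan.simulate as sim
from invscan.seq import random_sequence


@pytest.fixture(scope="session")
def toy_genome_pair():
    """Small genome pair with one inversion and background divergence."""
    spec = sim.GenomePairSpec(
        chromosomes={"chr5": 100_000},
        inversions=[("chr5", 40_000, 60_000)],
        snp_rate=0.002,
        seed=11,
    )
    return sim.generate_genome_pair(spec)


@pytest.fixture(scope="session")
def small_panel():
    """Two-deme panel with a planted divergence block and causal haplotype."""
    spec = sim.PopulationSpec(
        n_sites=3_000,
        chrom_length=400_000,
        f_background=0.05,
        f_block=0.6,
        block=(140_000, 280_000),
        marker_positions=(150_000, 250_000),
        causal_positions=(200_000, 200_400, 200_900, 201_500),
        missing_rate=0.02,
        seed=7,
    )
    gm, labels, truth = sim.simulate_population(spec)
    return spec, gm, labels, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def monomer139():
    return random_sequence(np.random.default_rng(42), 139)
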