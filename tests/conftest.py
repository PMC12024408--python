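"""Shared fixtures: tiny genomes, random pedigrees, a small simulated study."""

import numpy as np
import pytest

from herdsim.genome import GenomeSpec, build_genome_map
from herdsim.pedigree import Pedigree


def toy_genome(n_chr=2, chr_len=100.0, n_markers=40, n_qtl_per_chr=5,
               seed=11):
    spec = GenomeSpec(n_chromosomes=n_chr,
                      chr_lengths_cm=(chr_len,) * n_chr,
                      n_qtl_per_chr=n_qtl_per_chr)
    return build_genome_map(spec, n_markers, seed=seed)


@pytest.fixture
def small_genome():
    return toy_genome()


def random_pedigree(n, seed, founder_frac=0.3):
    """Random multi-generation pedigree with parents preceding offspring."""
    rng = np.random.default_rng(seed)
    n_founders = max(2, int(n * founder_frac))
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    sex = np.zeros(n, dtype=np.uint8)
    sex[rng.random(n) < 0.5] = 1
    if n >= 2:
        sex[:2] = [0, 1]  # guarantee both sexes among founders
    for i in range(n_founders, n):
        males = np.flatnonzero(sex[:i] == 0)
        females = np.flatnonzero(sex[:i] == 1)
        sire[i] = rng.choice(males) + 1
        dam[i] = rng.choice(females) + 1
    return Pedigree(ids=np.arange(1, n + 1), sire=sire, dam=dam, sex=sex)


@pytest.fixture(scope="session")
def small_dataset():
    """One reduced-scale breed-A-like dataset shared by evaluation tests."""
    from herdsim.evaluation import scaled_design, simulate_dataset
    design = scaled_design("A", scale=0.05, n_chromosomes=4,
                           n_historical_generations=60)
    return simulate_dataset(design, h2=0.5, seed=20260927)
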