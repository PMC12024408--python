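"""Breed founding, replacement/growth dynamics, selection response."""

import numpy as np
import pytest

from herdsim.breeding import (BreedConfig, BreedingError, found_breed,
                              round_half_up, run_breed, simulate_breed)
from herdsim.popsim import FEMALE, MALE, HistoricalPhasePlan, simulate_historical
from herdsim.trait import TraitArchitecture, sample_qtl_effects
from tests.conftest import toy_genome


@pytest.fixture(scope="module")
def history():
    genome = toy_genome(n_chr=2, n_markers=60, n_qtl_per_chr=10, seed=21)
    plan = HistoricalPhasePlan(((0, 120), (15, 40), (30, 200)))
    return genome, simulate_historical(genome, plan, 2.5e-5, seed=22)


def make_arch(genome, hist, h2=0.5, seed=23):
    p = hist.allele_frequencies(genome.qtl_idx)
    return sample_qtl_effects(genome.n_qtl, p, h2=h2, seed=seed)


class TestFounding:
    def test_counts_and_generation_reset(self, history):
        genome, hist = history
        cfg = BreedConfig("X", 10, 50)
        pop = found_breed(hist, cfg, seed=1)
        assert pop.n_animals == 60
        assert np.all(pop.generation == 0)
        assert np.all(pop.sire == 0) and np.all(pop.dam == 0)
        assert (pop.sex == MALE).sum() == 10
        assert (pop.sex == FEMALE).sum() == 50

    def test_sex_relaxation_allows_lopsided_founder_draws(self, history):
        """Founder sexes are assigned at the draw, so one sex may take more
        than half of the historical generation."""
        genome, hist = history
        cfg = BreedConfig("X", 10, 150)  # 150 > 200/2
        pop = found_breed(hist, cfg, seed=2)
        assert (pop.sex == FEMALE).sum() == 150

    def test_insufficient_candidates(self, history):
        genome, hist = history
        with pytest.raises(BreedingError):
            found_breed(hist, BreedConfig("X", 150, 100), seed=3)

    def test_same_seed_same_founders(self, history):
        genome, hist = history
        cfg = BreedConfig("X", 5, 20)
        a = found_breed(hist, cfg, seed=4)
        b = found_breed(hist, cfg, seed=4)
        assert np.array_equal(a.haplotypes, b.haplotypes)


class TestReplacementDynamics:
    def test_full_turnover_pool_is_top_ranked(self, history):
        genome, hist = history
        arch = make_arch(genome, hist)
        cfg = BreedConfig("X", 6, 30, n_generations=1, offspring_per_dam=2,
                          sire_replacement_rate=1.0, dam_replacement_rate=1.0)
        pop, tbv, phen = simulate_breed(hist, genome, cfg, arch, seed=5)
        cohort = pop.cohort(1)
        for sex, pool, n0 in ((MALE, pop.sire_pool, 6),
                              (FEMALE, pop.dam_pool, 30)):
            young = cohort[pop.sex[cohort] == sex]
            order = np.argsort(-phen[young], kind="stable")
            expected = set(pop.ids[young[order[:n0]]].tolist())
            assert set(pool.tolist()) == expected

    def test_zero_replacement_keeps_pool(self, history):
        genome, hist = history
        arch = make_arch(genome, hist)
        cfg = BreedConfig("X", 6, 30, n_generations=3,
                          sire_replacement_rate=0.0, dam_replacement_rate=0.0)
        pop, _, _ = simulate_breed(hist, genome, cfg, arch, seed=6)
        founders = pop.cohort(0)
        assert set(pop.sire_pool) == set(pop.ids[founders[:6]])
        assert set(pop.dam_pool) == set(pop.ids[founders[6:]])
        # one offspring per dam per cohort
        for g in (1, 2, 3):
            assert pop.cohort(g).size == 30

    def test_dam_growth_compounds(self, history):
        """Breed-C style dam growth: final pool = round(n0 * 1.355^10)."""
        genome, hist = history
        arch = make_arch(genome, hist)
        cfg = BreedConfig("X", 8, 20, n_generations=10, offspring_per_dam=3,
                          dam_replacement_rate=0.105, dam_growth_rate=0.355,
                          sire_replacement_rate=0.063, sire_growth_rate=0.0)
        pop, _, _ = simulate_breed(hist, genome, cfg, arch, seed=7)
        assert pop.dam_pool.size == round_half_up(20 * 1.355 ** 10)
        assert pop.sire_pool.size == 8


class TestRunBreed:
    def test_structure_and_outputs(self, history):
        genome, hist = history
        arch = make_arch(genome, hist)
        cfg = BreedConfig("X", 6, 30, n_generations=10,
                          sire_replacement_rate=0.5, dam_replacement_rate=0.3)
        ped, geno, phen = run_breed(hist, genome, cfg, arch, seed=8)
        # topological order is validated by the Pedigree constructor
        assert set(phen["generation"]) == {9, 10}
        assert geno.n_animals == len(phen)
        # every generation-10 animal has parents from the current pools,
        # which contain only earlier-generation animals
        gen = dict(zip(ped.ids.tolist(), np.asarray(ped.generation).tolist()))
        for _, row in phen[phen.generation == 10].iterrows():
            i = int(np.flatnonzero(ped.ids == row.animal_id)[0])
            assert gen[int(ped.sire[i])] < 10
            assert gen[int(ped.dam[i])] < 10

    def test_noiseless_selection_acts_on_tbv(self, history):
        genome, hist = history
        p = hist.allele_frequencies(genome.qtl_idx)
        arch = sample_qtl_effects(genome.n_qtl, p, h2=0.7, seed=30)
        arch = TraitArchitecture(beta=arch.beta, h2=1.0, sigma_a2=arch.sigma_a2,
                                 sigma_e2=0.0, qtl_variances=arch.qtl_variances)
        _, _, phen = run_breed(hist, genome,
                               BreedConfig("X", 6, 30, n_generations=3),
                               arch, seed=9, genotyped_generations=(2, 3))
        assert np.allclose(phen["phenotype"], phen["tbv"])

    def test_selection_response_is_positive(self, history):
        """Directional phenotypic selection raises mean TBV over cohorts."""
        genome, hist = history
        wins = 0
        for rep in range(10):
            arch = make_arch(genome, hist, h2=0.7, seed=40 + rep)
            cfg = BreedConfig("X", 6, 30, n_generations=10,
                              sire_replacement_rate=0.8,
                              dam_replacement_rate=0.5)
            pop, tbv, _ = simulate_breed(hist, genome, cfg, arch,
                                         seed=50 + rep)
            if tbv[pop.cohort(10)].mean() > tbv[pop.cohort(1)].mean():
                wins += 1
        assert wins >= 8

    def test_ebv_selection_mode_runs(self, history):
        genome, hist = history
        arch = make_arch(genome, hist)
        cfg = BreedConfig("X", 5, 15, n_generations=3,
                          selection_criterion="ebv")
        ped, geno, phen = run_breed(hist, genome, cfg, arch, seed=10,
                                    genotyped_generations=(2, 3))
        assert len(phen) == geno.n_animals > 0

    def test_config_validation(self):
        with pytest.raises(BreedingError):
            BreedConfig("X", 5, 5, sire_replacement_rate=1.2)
        with pytest.raises(BreedingError):
            BreedConfig("X", 5, 5, dam_growth_rate=-0.1)
        with pytest.raises(BreedingError):
            BreedConfig("X", 5, 5, selection_criterion="tallest")
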