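"""Recent-population (breed) simulation with selection and replacement.

A breed is founded by drawing animals from the last historical generation
and then bred for a fixed number of discrete offspring cohorts.  Separate
sire and dam breeding pools persist across cohorts: after each cohort is
born, a fraction of each pool (the replacement rate) is culled at random
and refilled with the top-ranked young candidates of that cohort, and pool
sizes compound by the sex-specific growth rate.  Each dam produces exactly
one offspring per cohort with a randomly assigned sire; ranking uses either
the candidate's own phenotype or a pedigree-BLUP EBV fitted to all records
available at that point.  Mutation is disabled in the recent generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import MarkerMap
from .pedigree import Pedigree
from .popsim import FEMALE, MALE, PopulationState, SimulationError, make_gametes
from .trait import TraitArchitecture, compute_tbv


class BreedingError(SimulationError):
    pass


@dataclass(frozen=True)
class BreedConfig:
    """Design of one breed's recent-population phase."""

    breed_label: str
    n_founder_males: int
    n_founder_females: int
    n_generations: int = 10
    offspring_per_dam: int = 1
    selection_criterion: str = "phenotype"      # "phenotype" | "ebv"
    sire_replacement_rate: float = 0.5
    dam_replacement_rate: float = 0.3
    sire_growth_rate: float = 0.0
    dam_growth_rate: float = 0.0

    def __post_init__(self):
        for r in (self.sire_replacement_rate, self.dam_replacement_rate):
            if not 0.0 <= r <= 1.0:
                raise BreedingError("replacement rates must be in [0, 1]")
        for g in (self.sire_growth_rate, self.dam_growth_rate):
            if g < 0.0:
                raise BreedingError("growth rates must be non-negative")
        if self.selection_criterion not in ("phenotype", "ebv"):
            raise BreedingError(
                f"unknown selection criterion {self.selection_criterion!r}")


#: Table-1 breed designs (founder counts, replacement and growth rates).
PAPER_BREEDS = {
    "A": BreedConfig("A", 620, 5800, sire_replacement_rate=0.5065,
                     sire_growth_rate=0.072, dam_replacement_rate=0.30,
                     dam_growth_rate=0.098),
    "B": BreedConfig("B", 350, 5100, sire_replacement_rate=0.1851,
                     sire_growth_rate=0.1038, dam_replacement_rate=0.3015,
                     dam_growth_rate=0.1629),
    "C": BreedConfig("C", 300, 5000, sire_replacement_rate=0.063,
                     sire_growth_rate=0.123, dam_replacement_rate=0.105,
                     dam_growth_rate=0.355),
}


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class BreedPopulation:
    """All animals of one breed's recent phase, founders included."""

    config: BreedConfig
    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    generation: np.ndarray
    haplotypes: np.ndarray
    sire_pool: np.ndarray = field(default_factory=lambda: np.array([], int))
    dam_pool: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def n_animals(self) -> int:
        return self.ids.size

    def positions(self, ids) -> np.ndarray:
        pos = {int(a): i for i, a in enumerate(self.ids)}
        return np.array([pos[int(a)] for a in np.atleast_1d(ids)])

    def cohort(self, generation: int) -> np.ndarray:
        """Row indices of one generation's animals."""
        return np.flatnonzero(self.generation == generation)

    def pedigree(self) -> Pedigree:
        return Pedigree(ids=self.ids, sire=self.sire, dam=self.dam,
                        sex=self.sex, generation=self.generation,
                        breed_label=self.config.breed_label)

    def state_slice(self, rows: np.ndarray) -> PopulationState:
        return PopulationState(
            ids=self.ids[rows], sire=self.sire[rows], dam=self.dam[rows],
            sex=self.sex[rows], generation=self.generation[rows],
            haplotypes=self.haplotypes[rows])


def found_breed(historical: PopulationState, cfg: BreedConfig,
                seed: int) -> BreedPopulation:
    """Draw breed founders at random (without replacement) from the last
    historical generation.

    Sexes are assigned at the founding draw (the unselected historical
    phase has an equal sex ratio, but founder counts per sex may exceed
    one sex's share of it, so historical sex labels are not binding).
    """
    n_need = cfg.n_founder_males + cfg.n_founder_females
    if n_need > historical.n_animals:
        raise BreedingError(
            f"breed {cfg.breed_label}: {n_need} founders requested from a "
            f"historical generation of {historical.n_animals}")
    rng = np.random.default_rng(seed)
    rows = rng.choice(historical.n_animals, size=n_need, replace=False)
    sex = np.concatenate([
        np.full(cfg.n_founder_males, MALE, dtype=np.uint8),
        np.full(cfg.n_founder_females, FEMALE, dtype=np.uint8)])
    ids = np.arange(1, n_need + 1, dtype=np.int64)
    pop = BreedPopulation(
        config=cfg,
        ids=ids,
        sire=np.zeros(n_need, dtype=np.int64),
        dam=np.zeros(n_need, dtype=np.int64),
        sex=sex,
        generation=np.zeros(n_need, dtype=np.int32),
        haplotypes=historical.haplotypes[rows].copy(),
    )
    pop.sire_pool = ids[:cfg.n_founder_males].copy()
    pop.dam_pool = ids[cfg.n_founder_males:].copy()
    return pop


def _pool_target(n0: int, growth: float, t: int) -> int:
    return max(1, round_half_up(n0 * (1.0 + growth) ** t))


def _update_pool(pool: np.ndarray, candidates: np.ndarray,
                 ranking: dict[int, float], replacement: float,
                 target: int, rng: np.random.Generator) -> np.ndarray:
    """Cull ``replacement`` of the pool at random, refill to ``target``
    with the top-ranked candidates."""
    n_keep = round_half_up((1.0 - replacement) * pool.size)
    n_keep = min(n_keep, target)
    keep = (rng.choice(pool, size=n_keep, replace=False)
            if n_keep < pool.size else pool.copy())
    n_new = target - n_keep
    if n_new > 0:
        if candidates.size == 0:
            raise BreedingError("no young candidates available for the pool")
        if n_new > candidates.size:
            import warnings
            warnings.warn(
                f"only {candidates.size} young candidates for {n_new} pool "
                "slots; pool will fall short of its target size")
        scores = np.array([ranking[int(a)] for a in candidates])
        order = np.argsort(-scores, kind="stable")
        recruits = candidates[order[:n_new]]
        keep = np.concatenate([keep, recruits])
    return keep


def advance_breed_generation(pop: BreedPopulation, genome: MarkerMap,
                             generation: int, rng: np.random.Generator,
                             recomb: np.ndarray | None = None) -> np.ndarray:
    """Mate the current pools to produce one offspring cohort.

    Returns the row indices of the new cohort.  Each dam produces
    ``offspring_per_dam`` offspring by a randomly assigned sire; offspring
    sex is Bernoulli(1/2); no mutation.
    """
    cfg = pop.config
    if pop.sire_pool.size == 0 or pop.dam_pool.size == 0:
        raise BreedingError("empty breeding pool")
    if recomb is None:
        recomb = genome.recomb_fractions()
    dams = np.repeat(pop.dam_pool, cfg.offspring_per_dam)
    sires = pop.sire_pool[rng.integers(0, pop.sire_pool.size, dams.size)]
    srows = pop.positions(sires)
    drows = pop.positions(dams)
    pat = make_gametes(pop.haplotypes[srows], recomb, rng)
    mat = make_gametes(pop.haplotypes[drows], recomb, rng)
    hap = np.stack([pat, mat], axis=1)
    n = dams.size
    next_id = int(pop.ids[-1]) + 1
    ids = np.arange(next_id, next_id + n, dtype=np.int64)
    sex = (rng.random(n) < 0.5).astype(np.uint8)  # MALE=0 / FEMALE=1
    start = pop.n_animals
    pop.ids = np.concatenate([pop.ids, ids])
    pop.sire = np.concatenate([pop.sire, sires])
    pop.dam = np.concatenate([pop.dam, dams])
    pop.sex = np.concatenate([pop.sex, sex])
    pop.generation = np.concatenate(
        [pop.generation, np.full(n, generation, dtype=np.int32)])
    pop.haplotypes = np.concatenate([pop.haplotypes, hap], axis=0)
    return np.arange(start, start + n)


def _ebv_ranking(pop: BreedPopulation, phenotype: np.ndarray,
                 recorded: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """Current-data pedigree-BLUP EBVs for every breed animal."""
    from .blup import solve_pblup
    ped = pop.pedigree()
    sol = solve_pblup(phenotype[recorded], pop.ids[recorded], ped,
                      lam=arch.lambda_ratio)
    return sol.u_hat


def simulate_breed(historical: PopulationState, genome: MarkerMap,
                   cfg: BreedConfig, arch: TraitArchitecture, seed: int,
                   ) -> tuple[BreedPopulation, np.ndarray, np.ndarray]:
    """Simulate one breed's recent phase; returns the full population with
    its final breeding pools plus per-animal TBV and phenotype arrays."""
    ss = np.random.SeedSequence(seed)
    found_seed, drive_seed = ss.spawn(2)
    pop = found_breed(historical, cfg,
                      found_seed.generate_state(1)[0] % (2 ** 31))
    rng = np.random.default_rng(drive_seed)
    recomb = genome.recomb_fractions()
    qtl = genome.qtl_idx

    def trait_values(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tbv = compute_tbv(pop.haplotypes[rows][:, :, qtl].sum(axis=1), arch)
        e = (rng.normal(0.0, np.sqrt(arch.sigma_e2), size=rows.size)
             if arch.sigma_e2 > 0 else np.zeros(rows.size))
        return tbv, arch.mu + tbv + e

    n_all = pop.n_animals
    tbv = np.empty(0)
    phen = np.empty(0)
    tbv0, phen0 = trait_values(np.arange(n_all))
    tbv, phen = tbv0, phen0

    n0_sires = cfg.n_founder_males
    n0_dams = cfg.n_founder_females
    for t in range(1, cfg.n_generations + 1):
        new_rows = advance_breed_generation(pop, genome, t, rng,
                                            recomb=recomb)
        tbv_t, phen_t = trait_values(new_rows)
        tbv = np.concatenate([tbv, tbv_t])
        phen = np.concatenate([phen, phen_t])

        if cfg.selection_criterion == "phenotype":
            score = phen
        else:
            recorded = np.arange(pop.n_animals)
            score = _ebv_ranking(pop, phen, recorded, arch)
        ranking = {int(a): float(s)
                   for a, s in zip(pop.ids[new_rows], score[new_rows])}
        young = pop.ids[new_rows]
        young_m = young[pop.sex[new_rows] == MALE]
        young_f = young[pop.sex[new_rows] == FEMALE]
        pop.sire_pool = _update_pool(
            pop.sire_pool, young_m, ranking, cfg.sire_replacement_rate,
            _pool_target(n0_sires, cfg.sire_growth_rate, t), rng)
        pop.dam_pool = _update_pool(
            pop.dam_pool, young_f, ranking, cfg.dam_replacement_rate,
            _pool_target(n0_dams, cfg.dam_growth_rate, t), rng)
    return pop, tbv, phen


def run_breed(historical: PopulationState, genome: MarkerMap,
              cfg: BreedConfig, arch: TraitArchitecture, seed: int,
              genotyped_generations: tuple[int, ...] | None = None,
              ) -> tuple[Pedigree, PopulationState, pd.DataFrame]:
    """Simulate one breed end to end.

    Returns the full recent pedigree, the genotyped slice (generations 9-10
    by default, i.e. the last two cohorts), and their phenotype table with
    columns animal_id, tbv, phenotype, generation, sex.  Phenotypes are
    simulated for every cohort (they drive phenotypic selection) but only
    the genotyped generations are reported, mirroring a design where older
    generations are neither genotyped nor recorded.
    """
    if genotyped_generations is None:
        genotyped_generations = (cfg.n_generations - 1, cfg.n_generations)
    pop, tbv, phen = simulate_breed(historical, genome, cfg, arch, seed)
    geno_rows = np.flatnonzero(np.isin(pop.generation,
                                       list(genotyped_generations)))
    table = pd.DataFrame({
        "animal_id": pop.ids[geno_rows],
        "tbv": tbv[geno_rows],
        "phenotype": phen[geno_rows],
        "generation": pop.generation[geno_rows],
        "sex": pop.sex[geno_rows],
    })
    return pop.pedigree(), pop.state_slice(geno_rows), table
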