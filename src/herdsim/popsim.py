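"""Forward-in-time population simulation (historical, neutral phase).

The historical phase evolves a randomly mating population of constant or
piecewise-linearly changing size for many discrete generations under drift
and recurrent (allele-flip) mutation, with no selection and no migration.
Its purpose is to build linkage disequilibrium and approach mutation-drift
equilibrium before breed formation.

Gametes are formed under the Haldane model (no crossover interference).
Rather than drawing Poisson crossover counts and uniform positions, meiosis
is simulated as the exact marginal of that process at the locus positions:
the copied parental haplotype switches between adjacent loci with
probability r = (1 - e^(-2d/100))/2 for map distance d cM, and restarts
with a fair coin at each chromosome.  The two formulations are identical in
law at the simulated loci, and the switching form vectorises over all
gametes of a generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import MarkerMap

MALE, FEMALE = 0, 1
NULL_ID = 0


class SimulationError(RuntimeError):
    pass


@dataclass
class PopulationState:
    """One generation (or cohort) of animals with phased genotypes.

    ``haplotypes`` has shape (n_animals, 2, n_loci) with alleles coded 0/1.
    ``sire``/``dam`` are animal IDs (0 = unknown/founder).
    """

    ids: np.ndarray          # int64
    sire: np.ndarray         # int64
    dam: np.ndarray          # int64
    sex: np.ndarray          # uint8, MALE/FEMALE
    generation: np.ndarray   # int32
    haplotypes: np.ndarray   # uint8 (n, 2, L)

    @property
    def n_animals(self) -> int:
        return self.ids.size

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def dosages(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Additive dosage (count of allele 1) per animal x locus."""
        h = self.haplotypes if loci is None else self.haplotypes[:, :, loci]
        return h.sum(axis=1, dtype=np.int8)

    def allele_frequencies(self, loci: np.ndarray | None = None) -> np.ndarray:
        h = self.haplotypes if loci is None else self.haplotypes[:, :, loci]
        return h.mean(axis=(0, 1))

    def mean_heterozygosity(self) -> float:
        """Mean expected heterozygosity 2p(1-p) across loci."""
        p = self.allele_frequencies()
        return float(np.mean(2.0 * p * (1.0 - p)))

    def sex_indices(self, sex: int) -> np.ndarray:
        return np.flatnonzero(self.sex == sex)


@dataclass(frozen=True)
class HistoricalPhasePlan:
    """Population-size breakpoints (generation, size) for the historical
    phase; sizes between breakpoints are linearly interpolated."""

    breakpoints: tuple[tuple[int, int], ...]

    def __post_init__(self):
        gens = [g for g, _ in self.breakpoints]
        if not gens or gens[0] != 0:
            raise SimulationError("plan must start at generation 0")
        if any(b >= a for b, a in zip(gens, gens[1:])):
            raise SimulationError("generation breakpoints must increase")
        if any(n < 2 for _, n in self.breakpoints):
            raise SimulationError("population size must be at least 2")

    @property
    def n_generations(self) -> int:
        return self.breakpoints[-1][0]

    def sizes(self) -> np.ndarray:
        """Per-generation size for generations 0..n_generations."""
        gens = np.array([g for g, _ in self.breakpoints])
        ns = np.array([n for _, n in self.breakpoints], dtype=float)
        out = np.interp(np.arange(self.n_generations + 1), gens, ns)
        return np.rint(out).astype(int)


def founder_population(genome: MarkerMap, n: int, seed: int,
                       start_id: int = 1) -> PopulationState:
    """Base population with alleles drawn independently at frequency 0.5.

    Sexes alternate so the split is as even as possible.
    """
    if n < 1:
        raise SimulationError("need at least one founder")
    rng = np.random.default_rng(seed)
    hap = (rng.random((n, 2, genome.n_loci)) < 0.5).astype(np.uint8)
    ids = np.arange(start_id, start_id + n, dtype=np.int64)
    sex = (np.arange(n) % 2).astype(np.uint8)
    return PopulationState(
        ids=ids,
        sire=np.zeros(n, dtype=np.int64),
        dam=np.zeros(n, dtype=np.int64),
        sex=sex,
        generation=np.zeros(n, dtype=np.int32),
        haplotypes=hap,
    )


def make_gametes(parent_haps: np.ndarray, recomb: np.ndarray,
                 rng: np.random.Generator,
                 mutation_rate: float = 0.0) -> np.ndarray:
    """Form one gamete per parental haplotype pair.

    ``parent_haps`` has shape (k, 2, L); returns (k, L).  ``recomb`` is the
    per-locus adjacent recombination fraction from
    :meth:`MarkerMap.recomb_fractions` (0.5 at chromosome starts, which also
    randomises the starting haplotype).
    """
    k, _, L = parent_haps.shape
    switch = rng.random((k, L)) < recomb[None, :]
    source = np.logical_xor.accumulate(switch, axis=1)
    gam = np.where(source, parent_haps[:, 1, :], parent_haps[:, 0, :])
    if mutation_rate > 0.0:
        flips = rng.random((k, L)) < mutation_rate
        gam = gam ^ flips
    return gam.astype(np.uint8, copy=False)


def random_mating_generation(pop: PopulationState, genome: MarkerMap,
                             n_offspring: int, generation: int,
                             rng: np.random.Generator,
                             mutation_rate: float,
                             next_id: int,
                             recomb: np.ndarray | None = None,
                             ) -> PopulationState:
    """One generation of random union of gametes with equal sex ratio."""
    males = pop.sex_indices(MALE)
    females = pop.sex_indices(FEMALE)
    if males.size == 0 or females.size == 0:
        raise SimulationError("both sexes required for mating")
    if recomb is None:
        recomb = genome.recomb_fractions()
    sires = males[rng.integers(0, males.size, size=n_offspring)]
    dams = females[rng.integers(0, females.size, size=n_offspring)]
    pat = make_gametes(pop.haplotypes[sires], recomb, rng, mutation_rate)
    mat = make_gametes(pop.haplotypes[dams], recomb, rng, mutation_rate)
    hap = np.stack([pat, mat], axis=1)
    ids = np.arange(next_id, next_id + n_offspring, dtype=np.int64)
    sex = (np.arange(n_offspring) % 2).astype(np.uint8)
    return PopulationState(
        ids=ids,
        sire=pop.ids[sires],
        dam=pop.ids[dams],
        sex=sex,
        generation=np.full(n_offspring, generation, dtype=np.int32),
        haplotypes=hap,
    )


def simulate_historical(genome: MarkerMap, plan: HistoricalPhasePlan,
                        mutation_rate: float, seed: int) -> PopulationState:
    """Evolve the historical population and return its final generation.

    Founders start at allele frequency 0.5 everywhere.  Each generation is a
    fresh random union of gametes (discrete generations, random mating,
    equal sex ratio); mutation flips alleles at ``mutation_rate`` per locus
    per gamete.
    """
    if not 0.0 <= mutation_rate < 1.0:
        raise SimulationError("mutation_rate must be in [0, 1)")
    sizes = plan.sizes()
    ss = np.random.SeedSequence(seed)
    founder_seed, mating_seed = ss.spawn(2)
    pop = founder_population(genome, int(sizes[0]),
                             founder_seed.generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(mating_seed)
    recomb = genome.recomb_fractions()
    next_id = int(pop.ids[-1]) + 1
    for t in range(1, sizes.size):
        pop = random_mating_generation(
            pop, genome, int(sizes[t]), t, rng, mutation_rate, next_id,
            recomb=recomb)
        next_id = int(pop.ids[-1]) + 1
    return pop


def r_squared(hapA: np.ndarray, hapB: np.ndarray) -> float:
    """Squared LD correlation r^2 = D^2 / (pA qA pB qB) from phased
    haplotype vectors (one entry per haplotype)."""
    pA = hapA.mean()
    pB = hapB.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic locus has undefined r^2")
    p11 = np.mean((hapA == 1) & (hapB == 1))
    D = p11 - pA * pB
    return float(D * D / (pA * (1 - pA) * pB * (1 - pB)))


def ld_summary(pop: PopulationState, genome: MarkerMap,
               max_dist_cm: float, n_bins: int = 10,
               loci: np.ndarray | None = None) -> pd.DataFrame:
    """Mean pairwise r^2 binned by map distance, within chromosomes.

    Monomorphic loci are excluded.  Returns an empty table (with a warning)
    if fewer than two loci segregate.
    """
    if loci is None:
        loci = np.arange(genome.n_loci)
    hap = pop.haplotypes[:, :, loci].reshape(-1, loci.size).astype(float)
    p = hap.mean(axis=0)
    seg = (p > 0) & (p < 1)
    cols = np.flatnonzero(seg)
    empty = pd.DataFrame(columns=["dist_lo", "dist_hi", "mean_r2", "n_pairs"])
    if cols.size < 2:
        import warnings
        warnings.warn("fewer than two segregating loci; empty LD table")
        return empty
    chrom = genome.chrom[loci][cols]
    pos = genome.pos_cm[loci][cols]
    h = hap[:, cols]
    hc = h - h.mean(axis=0)
    denom = np.sqrt((hc ** 2).mean(axis=0))
    z = hc / denom

    edges = np.linspace(0.0, max_dist_cm, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    n_hap = h.shape[0]
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if idx.size < 2:
            continue
        # correlation matrix of haplotype indicators = r; r^2 is LD measure
        corr = (z[:, idx].T @ z[:, idx]) / n_hap
        d = np.abs(pos[idx][:, None] - pos[idx][None, :])
        iu = np.triu_indices(idx.size, k=1)
        dv, rv = d[iu], corr[iu] ** 2
        keep = dv <= max_dist_cm
        which = np.minimum(
            np.searchsorted(edges, dv[keep], side="right") - 1, n_bins - 1)
        np.add.at(sums, which, rv[keep])
        np.add.at(counts, which, 1)
    rows = counts > 0
    if not rows.any():
        import warnings
        warnings.warn("no locus pairs within max_dist_cm; empty LD table")
        return empty
    return pd.DataFrame({
        "dist_lo": edges[:-1][rows],
        "dist_hi": edges[1:][rows],
        "mean_r2": sums[rows] / counts[rows],
        "n_pairs": counts[rows],
    })
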