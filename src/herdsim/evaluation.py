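"""Scenario-grid orchestration: simulate, fit, and score prediction methods.

A *scenario* is one cell of the study grid: (breed, heritability, marker
density, reference-population size, method).  For each cell the pipeline
quality-controls the genotypes, splits generations 9-10 into a reference
(training) and a generation-10 validation set, fits PBLUP / GBLUP / wGBLUP
with the validation phenotypes masked, and scores prediction accuracy as
the Pearson correlation between true and estimated breeding values of the
validation animals.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .blup import solve_gblup, solve_pblup
from .breeding import PAPER_BREEDS, BreedConfig, run_breed
from .genome import (GenomeSpec, MarkerMap, bovine_chr_lengths,
                     build_genome_map)
from .kinship import grm
from .pedigree import Pedigree
from .popsim import HistoricalPhasePlan, PopulationState, simulate_historical
from .qc import GenotypeMatrix, QCThresholds, apply_qc
from .trait import TraitArchitecture, sample_qtl_effects
from .wgblup import WindowWeightConfig, wgblup_predict

METHODS = ("PBLUP", "GBLUP", "wGBLUP")

#: Historical phase plans per breed (generation, size) breakpoints.
PAPER_PLANS = {
    "A": ((0, 10_000), (500, 1_000), (1000, 7_120)),
    "B": ((0, 5_000), (500, 3_000), (1000, 7_120)),
    "C": ((0, 1_000), (500, 4_000), (1000, 7_120)),
}

PAPER_MUTATION_RATE = 2.5e-5


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class StudyDesign:
    """Everything needed to simulate one breed x density dataset."""

    genome_spec: GenomeSpec
    density: str | int
    historical_plan: HistoricalPhasePlan
    breed: BreedConfig
    mutation_rate: float = PAPER_MUTATION_RATE
    gamma_shape: float = 0.4


def paper_design(breed: str = "A", density: str = "50k") -> StudyDesign:
    """The full-scale study design for one breed and chip density."""
    return StudyDesign(
        genome_spec=GenomeSpec(),
        density=density,
        historical_plan=HistoricalPhasePlan(PAPER_PLANS[breed]),
        breed=PAPER_BREEDS[breed],
    )


def scaled_design(breed: str = "A", scale: float = 0.1,
                  n_markers: int | None = None,
                  n_historical_generations: int = 100,
                  n_chromosomes: int = 29,
                  n_qtl_per_chr: int = 25,
                  selection_criterion: str = "phenotype") -> StudyDesign:
    """Reduced-scale analog of a breed design.

    ``scale`` multiplies historical sizes and founder counts; the
    historical phase is compressed to ``n_historical_generations`` with the
    bottleneck/expansion at its midpoint.  To keep the marker density per
    centimorgan (and with it the marker-QTL linkage disequilibrium that
    genomic prediction exploits) comparable to the full design, shrink the
    genome via ``n_chromosomes`` together with the panel instead of
    thinning markers across the full map.  ``n_markers`` defaults to the
    50k panel scaled by the included genome share and by ``scale``.
    """
    if not 0 < scale <= 1:
        raise EvaluationError("scale must be in (0, 1]")
    base = PAPER_BREEDS[breed]
    plan0 = PAPER_PLANS[breed]
    g_mid = n_historical_generations // 2
    sizes = [max(8, round(n * scale)) for _, n in plan0]
    plan = HistoricalPhasePlan((
        (0, sizes[0]), (g_mid, sizes[1]),
        (n_historical_generations, sizes[2])))
    cfg = replace(
        base,
        n_founder_males=max(2, round(base.n_founder_males * scale)),
        n_founder_females=max(2, round(base.n_founder_females * scale)),
        selection_criterion=selection_criterion,
    )
    spec = GenomeSpec(n_chromosomes=n_chromosomes,
                      chr_lengths_cm=tuple(bovine_chr_lengths(n_chromosomes)),
                      n_qtl_per_chr=n_qtl_per_chr)
    if n_markers is None:
        share = spec.total_cm / GenomeSpec().total_cm
        n_markers = max(n_chromosomes, round(58_990 * share * scale))
    return StudyDesign(
        genome_spec=spec,
        density=n_markers,
        historical_plan=plan,
        breed=cfg,
    )


@dataclass
class SimulatedDataset:
    """One simulated breed x density dataset ready for evaluation."""

    design: StudyDesign
    h2: float
    genome: MarkerMap
    arch: TraitArchitecture
    pedigree: Pedigree
    genotyped: PopulationState      # generations 9-10
    phenotypes: pd.DataFrame        # animal_id, tbv, phenotype, generation, sex
    seed: int
    _qc_cache: tuple | None = field(default=None, repr=False)

    def marker_genotypes(self) -> GenotypeMatrix:
        idx = self.genome.marker_idx
        return GenotypeMatrix(
            dosages=self.genotyped.dosages(idx),
            animal_ids=self.genotyped.ids,
            locus_ids=self.genome.locus_ids[idx],
            chrom=self.genome.chrom[idx],
            pos_cm=self.genome.pos_cm[idx],
        )

    def qc_markers(self, thresholds: QCThresholds = QCThresholds()
                   ) -> GenotypeMatrix:
        if self._qc_cache is not None and self._qc_cache[0] == thresholds:
            return self._qc_cache[1]
        filtered, _ = apply_qc(self.marker_genotypes(), thresholds)
        self._qc_cache = (thresholds, filtered)
        return filtered


def simulate_dataset(design: StudyDesign, h2: float, seed: int
                     ) -> SimulatedDataset:
    """Simulate genome -> historical population -> trait -> breed."""
    ss = np.random.SeedSequence(seed)
    s_map, s_hist, s_arch, s_breed = (
        s.generate_state(1)[0] % (2 ** 31) for s in ss.spawn(4))
    genome = build_genome_map(design.genome_spec, design.density, s_map)
    hist = simulate_historical(genome, design.historical_plan,
                               design.mutation_rate, s_hist)
    qtl_freqs = hist.allele_frequencies(genome.qtl_idx)
    arch = sample_qtl_effects(genome.n_qtl, qtl_freqs, h2,
                              shape=design.gamma_shape, seed=s_arch)
    ped, genotyped, phen = run_breed(hist, genome, design.breed, arch,
                                     s_breed)
    return SimulatedDataset(design=design, h2=h2, genome=genome, arch=arch,
                            pedigree=ped, genotyped=genotyped,
                            phenotypes=phen, seed=seed)


@dataclass(frozen=True)
class ScenarioConfig:
    """One grid cell: breed x h2 x density x RP size x method."""

    breed_label: str
    h2: float
    density: str | int
    rp_size: int
    method: str
    replicate_seed: int
    n_validation: int = 100
    window: WindowWeightConfig = WindowWeightConfig()
    blend: float = 0.01

    def __post_init__(self):
        if self.method not in METHODS:
            raise EvaluationError(f"unknown method {self.method!r}")

    def key(self) -> str:
        raw = (f"{self.breed_label}|{self.h2}|{self.density}|{self.rp_size}|"
               f"{self.method}|{self.replicate_seed}|{self.n_validation}|"
               f"{self.window.S}|{self.window.n_passes}|{self.blend}")
        return hashlib.sha1(raw.encode()).hexdigest()[:12]


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    accuracy: float
    n_reference: int
    n_validation: int
    solver: str = ""
    converged: bool = True

    def row(self) -> dict:
        c = self.config
        return {
            "key": c.key(), "breed": c.breed_label, "h2": c.h2,
            "density": str(c.density), "rp_size": c.rp_size,
            "method": c.method, "replicate_seed": c.replicate_seed,
            "accuracy": self.accuracy, "n_reference": self.n_reference,
            "n_validation": self.n_validation, "converged": self.converged,
        }


def split_reference_validation(candidates: pd.DataFrame, rp_size: int,
                               n_validation: int, seed: int,
                               validation_generation: int | None = None
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Random validation set from the last genotyped generation, reference
    from the remaining candidates.

    Both sets are drawn from a seed-determined permutation, so reference
    sets for increasing ``rp_size`` at the same seed are nested.
    """
    gen = candidates["generation"]
    if validation_generation is None:
        validation_generation = int(gen.max())
    rng = np.random.default_rng(seed)
    last = candidates.loc[gen == validation_generation, "animal_id"].to_numpy()
    if n_validation > last.size:
        raise EvaluationError(
            f"validation size {n_validation} exceeds the "
            f"{last.size} generation-{validation_generation} candidates")
    val = rng.permutation(last)[:n_validation]
    rest = candidates.loc[~candidates["animal_id"].isin(val),
                          "animal_id"].to_numpy()
    if rp_size > rest.size:
        raise EvaluationError(
            f"reference size {rp_size} exceeds the {rest.size} remaining "
            f"candidates (short by {rp_size - rest.size})")
    ref = rng.permutation(rest)[:rp_size]
    return ref, val


def accuracy(tbv: np.ndarray, ebv: np.ndarray) -> float:
    """Prediction accuracy: Pearson correlation of TBV and (G)EBV."""
    tbv = np.asarray(tbv, float)
    ebv = np.asarray(ebv, float)
    if tbv.size != ebv.size:
        raise EvaluationError("TBV and EBV lengths differ")
    if tbv.size < 3:
        raise EvaluationError("need at least 3 pairs for a correlation")
    if np.std(tbv) == 0 or np.std(ebv) == 0:
        raise EvaluationError("zero variance makes accuracy undefined")
    return float(np.corrcoef(tbv, ebv)[0, 1])


def run_scenario(cfg: ScenarioConfig, ds: SimulatedDataset,
                 thresholds: QCThresholds = QCThresholds()) -> ScenarioResult:
    """Fit one method on one reference/validation split and score it.

    Validation phenotypes never enter the fit: the response vector passed
    to every solver is restricted to reference animals.
    """
    cand = ds.phenotypes
    ref_ids, val_ids = split_reference_validation(
        cand, cfg.rp_size, cfg.n_validation, cfg.replicate_seed)
    by_id = cand.set_index("animal_id")
    y_ref = by_id.loc[ref_ids, "phenotype"].to_numpy()
    tbv_val = by_id.loc[val_ids, "tbv"].to_numpy()
    lam = ds.arch.lambda_ratio

    if cfg.method == "PBLUP":
        sol = solve_pblup(y_ref, ref_ids, ds.pedigree, lam=lam)
        pred = sol.predictions(val_ids)
    else:
        g = ds.qc_markers(thresholds)
        if g.n_loci == 0:
            raise EvaluationError("no markers survived quality control")
        gpos = {int(a): i for i, a in enumerate(g.animal_ids)}
        ref_rows = np.array([gpos[int(a)] for a in ref_ids])
        val_rows = np.array([gpos[int(a)] for a in val_ids])
        if cfg.method == "GBLUP":
            rows = np.concatenate([ref_rows, val_rows])
            ids = np.concatenate([ref_ids, val_ids])
            G = grm(g.dosages[rows], ids=ids)
            sol = solve_gblup(y_ref, ref_ids, G, lam=lam, blend=cfg.blend)
            pred = sol.predictions(val_ids)
        else:  # wGBLUP
            sol, _ = wgblup_predict(
                y_ref, g.dosages[ref_rows], g.dosages[val_rows],
                cfg.window, lam_g=lam, chrom=g.chrom)
            pred = sol.extras["gebv_predict"]

    return ScenarioResult(
        config=cfg,
        accuracy=accuracy(tbv_val, pred),
        n_reference=ref_ids.size,
        n_validation=val_ids.size,
        solver=sol.diagnostics.method,
        converged=sol.diagnostics.converged,
    )


def grid_configs(breeds, h2s, densities, rp_sizes, methods=METHODS,
                 replicate_seeds=(1,), **kwargs) -> list[ScenarioConfig]:
    """Full-factorial list of scenario configurations."""
    out = []
    for b in breeds:
        for h2 in h2s:
            for d in densities:
                for rp in rp_sizes:
                    for m in methods:
                        for s in replicate_seeds:
                            out.append(ScenarioConfig(
                                breed_label=b, h2=h2, density=d, rp_size=rp,
                                method=m, replicate_seed=s, **kwargs))
    return out


def run_grid(configs: list[ScenarioConfig], dataset_provider,
             cache_path=None) -> pd.DataFrame:
    """Run every scenario, skipping cells already present in the cache.

    ``dataset_provider(cfg)`` returns the SimulatedDataset for a config
    (shared across methods/RP sizes as it sees fit).  Failures are recorded
    per cell and the grid continues.
    """
    done: dict[str, dict] = {}
    if cache_path is not None:
        import os
        if os.path.exists(cache_path):
            prev = pd.read_csv(cache_path, dtype={"density": str})
            done = {r["key"]: dict(r) for _, r in prev.iterrows()}
    rows = list(done.values())
    for cfg in configs:
        if cfg.key() in done:
            continue
        try:
            res = run_scenario(cfg, dataset_provider(cfg))
            row = res.row()
        except Exception as e:  # noqa: BLE001 - grid must keep going
            warnings.warn(f"scenario {cfg} failed: {e}")
            row = {**ScenarioResult(cfg, np.nan, 0, 0).row(),
                   "error": str(e)}
        rows.append(row)
        if cache_path is not None:
            pd.DataFrame(rows).to_csv(cache_path, index=False)
    return pd.DataFrame(rows)


def summarize_grid(results: pd.DataFrame) -> pd.DataFrame:
    """Per-cell replicate means and standard errors."""
    keys = ["breed", "h2", "density", "rp_size", "method"]
    g = results.groupby(keys)["accuracy"]
    out = g.agg(["mean", "count"])
    out["se"] = g.sem()
    return out.reset_index().rename(columns={"mean": "accuracy"})


def density_gain(table: pd.DataFrame, breed, rp_size, h2, method,
                 low: str = "50k", high: str = "770k") -> float:
    """Accuracy difference (high - low density) in percentage points."""
    sel = (
        (table["breed"] == breed) & (table["rp_size"] == rp_size)
        & (table["h2"] == h2) & (table["method"] == method))
    cells = table.loc[sel].set_index(table.loc[sel, "density"].astype(str))
    try:
        lo = float(cells.loc[str(low), "accuracy"])
        hi = float(cells.loc[str(high), "accuracy"])
    except KeyError as e:
        raise EvaluationError(
            f"missing density cell {e} for ({breed}, {rp_size}, {h2}, "
            f"{method})") from e
    return (hi - lo) * 100.0


def method_gain(table: pd.DataFrame, breed, rp_size, h2, density,
                method_hi: str, method_lo: str) -> float:
    """Accuracy difference between two methods, in percentage points."""
    sel = (
        (table["breed"] == breed) & (table["rp_size"] == rp_size)
        & (table["h2"] == h2) & (table["density"].astype(str) == str(density)))
    cells = table.loc[sel].set_index("method")
    try:
        hi = float(cells.loc[method_hi, "accuracy"])
        lo = float(cells.loc[method_lo, "accuracy"])
    except KeyError as e:
        raise EvaluationError(f"missing method cell {e}") from e
    return (hi - lo) * 100.0


def plot_accuracy_vs_rp(summary: pd.DataFrame, breed, h2, ax=None):
    """Accuracy-vs-reference-size curves, one line per method x density."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    sel = summary[(summary["breed"] == breed) & (summary["h2"] == h2)]
    for (method, density), sub in sel.groupby(["method", "density"]):
        sub = sub.sort_values("rp_size")
        ax.plot(sub["rp_size"], sub["accuracy"], marker="o",
                label=f"{method} ({density})")
    ax.set_xlabel("reference population size")
    ax.set_ylabel("accuracy corr(TBV, EBV)")
    ax.set_title(f"breed {breed}, h2 = {h2}")
    ax.legend()
    return ax
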