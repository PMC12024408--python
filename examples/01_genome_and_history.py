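"""Build a cattle-style genome map and evolve a historical population.

Prints the panel composition and shows that the bottleneck/expansion
history leaves linkage disequilibrium between nearby markers — the signal
genomic prediction will later exploit.
"""

import numpy as np

from herdsim import (GenomeSpec, HistoricalPhasePlan, build_genome_map,
                     ld_summary, simulate_historical)

# reduced-scale genome: first 5 autosomes, 800 markers, 25 QTL per chromosome
spec = GenomeSpec(n_chromosomes=5)
genome = build_genome_map(spec, 800, seed=1)
print(f"genome: {spec.n_chromosomes} chromosomes, "
      f"{spec.total_cm:.1f} cM, {genome.n_markers} markers, "
      f"{genome.n_qtl} QTL")

# 1/10-scale analog of the breed-A history: 1000 -> bottleneck -> expansion
plan = HistoricalPhasePlan(((0, 1000), (50, 100), (100, 712)))
pop = simulate_historical(genome, plan, mutation_rate=2.5e-5, seed=2)
print(f"final historical generation: {pop.n_animals} animals, "
      f"mean heterozygosity {pop.mean_heterozygosity():.3f}")

ld = ld_summary(pop, genome, max_dist_cm=10.0, n_bins=5)
print("\nLD decay (mean r^2 by map distance):")
print(ld.round(4).to_string(index=False))
print("\nAdjacent markers sit in higher LD than distant ones; the decay "
      "reflects the drift/bottleneck history of the population.")
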