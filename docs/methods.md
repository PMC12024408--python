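# Methods

This note documents the models implemented in `herdsim`, the defaults and
why they were chosen, what the simulator does and does not emulate, and
the numerical choices that affect results.

## Genome and map

The default genome is 29 autosomes whose genetic lengths are proportional
to the ARS-UCD1.2 physical assembly sizes, rescaled to a total of
2,715.85 cM (a config switch selects 2,486 cM; the two totals circulate
for the cattle map and the assembly-derived figure is the default).
Marker panels of 58,990 (50k) and 777,962 (770k) biallelic SNPs are
apportioned to chromosomes by the largest-remainder rule on chromosome
length — counts are exact and no chromosome deviates from proportionality
by more than one marker — and positions are uniform within chromosomes.
Twenty-five QTL per chromosome sit at the midpoints of 25 equal bins
(725 genome-wide). Base-pair positions for PLINK output are derived as
round(cM × 10⁶), i.e. the 1 cM ≈ 1 Mb cattle convention.

## Gamete model

Crossovers follow Haldane's model: counts per chromosome are Poisson with
mean length/100 and positions are uniform, with no interference. The
implementation simulates the exact marginal of that process at the locus
positions: the transmitted parental strand switches between adjacent loci
with probability r = (1 − e^(−2d/100))/2 and restarts with a fair coin at
each chromosome. This is identical in law to drawing crossover points
(for the loci actually simulated) and vectorises over every gamete of a
generation, which is what makes 1,000-generation histories cheap.
Recurrent mutation flips alleles at 2.5 × 10⁻⁵ per locus per gamete
during the historical phase and is off in the 10 recent generations,
where its expected contribution is negligible; both are configurable.

## Historical phase

Founders start at allele frequency 0.5, alleles i.i.d. per haplotype;
population size follows (generation, size) breakpoints with per-
generation linear interpolation (e.g. breed A: 10,000 at generation 0,
1,000 at 500, 7,120 at 1,000). Mating is random with equal sex ratio,
discrete generations, no selection, no migration. The phase exists to
build LD and approach mutation–drift equilibrium; the test suite checks
the Wright–Fisher decay E[H_t] = H₀(1 − 1/(2N))^t and that bottlenecked
populations show elevated LD between linked markers.

## Trait

Absolute QTL effects are Gamma(shape 0.4, scale 1) — heavy-tailed, so a
few QTL are large — with signs ± at probability ½ (an all-positive mode
exists). One common constant rescales β so Σ 2pⱼ(1−pⱼ)βⱼ² equals
h² × 1.0 exactly, with p taken from the last historical generation: the
breeds share one β vector and diverge only in QTL frequencies, so
per-breed genetic variances differ naturally. QTL monomorphic in the base
contribute nothing to the sum; if all are monomorphic, scaling fails
loudly. Per-QTL variance contributions are reported and can be flagged
against a cap (0.02 is the reference point used in the tests).
TBV is the exact dosage–effect product; phenotypes add N(0, 1−h²) noise
and a fixed overall mean (default 0), the model's only fixed effect.

## Breeds and selection

Each breed keeps separate sire and dam pools that persist across cohorts.
After each cohort is born, a replacement-rate fraction of each pool is
culled at random and refilled with the top-ranked young candidates, and
the pool target compounds by the sex-specific growth rate:
target_t = round(n₀(1+g)^t), computed from the founder count so rounding
does not accumulate. Each dam leaves exactly one offspring per cohort
(configurable), sires are assigned to dams at random, and offspring sex
is Bernoulli(½). Ranking is the candidate's own phenotype or a
pedigree-BLUP EBV refit each generation on all records so far; EBV
selection is the default for paper-faithful designs and phenotype
selection the cheap alternative. Founder sexes are assigned at the
founding draw, because the printed per-sex founder counts can exceed one
sex's share of the equal-ratio historical generation.

A design property worth knowing: with *phenotypic* mass selection the
PBLUP validation accuracy can *decrease* from h² 0.5 to 0.7 at reduced
scale (paired-replicate difference −0.026 ± 0.016 in our design checks),
because stronger own-performance selection erodes the between-family
variance that parent-average prediction uses; under EBV selection the
difference is positive (+0.039 ± 0.018). The study-level checks therefore
run the EBV-selection design.

## Quality control

Filters run in a fixed order — animal call rate, locus call rate,
MAF ≥ 0.05, exact HWE p ≥ 10⁻⁵ — and the whole sequence repeats until it
removes nothing, because dropping loci changes the remaining animals'
missing fractions; the fixed point makes QC idempotent and the per-filter
counts deterministic. "Call rate < 0.10" criteria are implemented as
"missing fraction > 0.10". The HWE test is the standard exact
enumeration over heterozygote counts given allele counts (no mid-p),
applied to all animals pooled; the population is structured, so the
threshold is deliberately lax. Simulated panels have no missing data, so
the call-rate filters are no-ops there.

## Relationship matrices and solvers

A is built by the tabular method; A⁻¹ directly by Henderson's rules with
Meuwissen–Luo inbreeding coefficients (sparse, never via inverting A).
G defaults to VanRaden's first method, G = ZZ′/Σ2pᵢ(1−pᵢ) with Z the
dosage matrix centered by 2p; the uncentered MM′ form is available
behind a flag but is not a relationship matrix and is not used by the
estimators. Centering frequencies default to those observed in the
genotyped set; note that with observed frequencies centered scores sum
to zero and G is exactly singular, which is why the solver stabilizes
G as 0.99·G + 0.01·I by default (configurable; oracle tests that need
exact equivalences pass blend 0 and external frequencies).

The mixed-model equations are solved by Jacobi-preconditioned conjugate
gradients to relative residual 10⁻⁸ (max 10n iterations) or by a dense
direct solve for small systems and oracles; non-convergence returns
diagnostics and warns, never silently. SNP-BLUP standardizes genotype
columns by √(2p(1−p)), excludes zero-weight and zero-variance markers
(their effects are exactly 0), and solves the ridge system with penalty
λ·W⁻¹. GBLUP with G built from the standardized design and
λ_snp = m·λ_g is algebraically identical to SNP-BLUP backsolving, and
the test suite enforces that equivalence.

## wGBLUP

Two passes (the described scheme): SNP-BLUP with W = I, then weights
Wⱼⱼ = C · mean(α̂ₖ², k ∈ [j−S, j+S]) with C fixing mean(W) = 1, then a
refit with diag(W). Windows truncate at chromosome and panel boundaries
with the actual window size as divisor, so edge markers are not
systematically down-weighted. S defaults to 10 (a 21-SNP window): the
window size is not pinned down by the source design — published
weighted-GRM windows range from tens to ~100 SNPs — so S is a first-class
knob recorded with every result. All-zero effect estimates fall back to
W = 1. λ is held fixed between passes; further passes are available but
off by default. The GRM route (weighted G with the standardized scaling,
then GBLUP) and the SNP-effect route agree to solver tolerance.

## Evaluation design

Candidates are the genotyped, phenotyped animals of generations 9–10.
Validation is a random subset of generation 10 (sizes in the tests: 100
to 300), drawn per replicate and shared across methods and reference
sizes, so method contrasts are paired; reference sets are prefixes of a
seed-determined permutation of the remaining candidates, hence nested
across reference sizes. Validation phenotypes never enter any fit — the
response vector passed to the solvers is restricted to reference animals,
and a test corrupts masked phenotypes to prove predictions are unchanged.
Accuracy is the Pearson correlation between TBV and prediction on the
validation set only; variance components are taken from simulation truth
(σa² = h², σe² = 1 − h²), as the estimators in the emulated study were
fed a known-heritability trait.

## Reduced-scale study conditions

Full-scale runs (7,120-animal historical endpoint, 777,962 SNPs, 1,000
historical generations, reference sizes to 15,000) are out of desk-scale
scope; the study-level checks run a breed-A analog chosen once as
realistic for the reduced size: founder counts at 1/10 (62 sires / 580
dams), 100 historical generations (1,000 → 100 → 712), the genome's
first five autosomes (≈716 cM), and the 50k panel scaled by the same
genome share and population scale (1,555 markers ≈ 2.2/cM). Shrinking
the genome together with the panel keeps marker–QTL LD realistic;
thinning 59k markers across the full 2,716 cM map would destroy the LD
genomic prediction depends on and reverse the method ordering for
artifactual reasons. The grid uses reference sizes {400, 900}, validation
300, heritabilities {0.3, 0.5, 0.7}, 14 paired replicates, EBV selection.
At this scale absolute accuracies (≈0.2–0.55) sit well below the
full-scale study's (≈0.56–0.90) — small reference sets and stronger
drift — so the checks are orderings, not levels: genomic beats pedigree
prediction cell-by-cell, accuracy rises with h² (pooled over reference
sizes, the level at which the finding is stated), and more reference
animals never hurt PBLUP/GBLUP at h² ≤ 0.5. The sparse-architecture
advantage of wGBLUP is checked on unlinked-locus toys with 5 causal loci
among 500 markers, where the weighting signal is unambiguous.

## What the simulator does not emulate

Sex chromosomes, multi-allelic loci, CNVs, migration between historical
lines, overlapping-generation age structure beyond the persistent
breeding pools, litter sizes above the configured offspring-per-dam,
performance-based culling, dominance/epistasis/maternal effects,
genotype-by-environment, and REML variance-component estimation (the
variance ratio comes from simulation truth). Passing tests therefore
show that the estimators behave correctly under an additive,
known-variance world with clean genotypes; they do not certify behavior
under model misspecification, pedigree errors, or real LD architectures.

## Numerical conventions

Rounding of pool sizes is round-half-up. Random draws flow from
`numpy.random.SeedSequence` spawns, so every artifact is bit-reproducible
from one integer seed, and solvers contain no randomness. The exact HWE
p-value is computed in log space and is stable for the cohort sizes
used. Degenerate inputs raise typed errors (empty pools, monomorphic
panels, infeasible splits name the shortfall); an emptied QC panel warns
and returns an empty matrix so grid runs can record the failure and
continue.
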