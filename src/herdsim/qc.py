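"""PLINK-style genotype quality control.

Filters, applied in a fixed order so removal counts are deterministic:
animal missingness > threshold, locus missingness > threshold, minor allele
frequency below threshold, and Hardy-Weinberg exact-test p-value below
threshold.  The simulated panels carry no missing genotypes, so on
simulator output the missingness filters are no-ops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

MISSING = -1


class QCError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Additive dosages (0/1/2, -1 = missing) with animal and locus labels."""

    dosages: np.ndarray          # int8 (n_animals x n_loci)
    animal_ids: np.ndarray
    locus_ids: np.ndarray
    chrom: np.ndarray | None = None
    pos_cm: np.ndarray | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise QCError("dosages must be a 2-D matrix")
        if self.dosages.shape != (len(self.animal_ids), len(self.locus_ids)):
            raise QCError("dosage shape inconsistent with labels")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of the counted allele, ignoring missing genotypes."""
        d = np.ma.masked_equal(self.dosages, MISSING)
        return np.asarray(d.mean(axis=0) / 2.0)

    def subset(self, animals: np.ndarray | None = None,
               loci: np.ndarray | None = None) -> "GenotypeMatrix":
        a = slice(None) if animals is None else animals
        l = slice(None) if loci is None else loci
        return GenotypeMatrix(
            dosages=self.dosages[a][:, l],
            animal_ids=np.asarray(self.animal_ids)[a],
            locus_ids=np.asarray(self.locus_ids)[l],
            chrom=None if self.chrom is None else np.asarray(self.chrom)[l],
            pos_cm=None if self.pos_cm is None else np.asarray(self.pos_cm)[l],
        )


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds; call-rate criteria are expressed as the
    maximum tolerated missing fraction (call rate below 90% excludes)."""

    maf_min: float = 0.05
    locus_missing_max: float = 0.10
    animal_missing_max: float = 0.10
    hwe_p_min: float = 1e-5

    def __post_init__(self):
        for v in (self.maf_min, self.locus_missing_max,
                  self.animal_missing_max, self.hwe_p_min):
            if not 0.0 <= v <= 1.0:
                raise QCError("thresholds must be in [0, 1]")


@dataclass
class QCReport:
    thresholds: QCThresholds
    n_animals_in: int = 0
    n_loci_in: int = 0
    removed_animals_missing: int = 0
    removed_loci_missing: int = 0
    removed_loci_maf: int = 0
    removed_loci_hwe: int = 0

    @property
    def n_animals_out(self) -> int:
        return self.n_animals_in - self.removed_animals_missing

    @property
    def n_loci_out(self) -> int:
        return (self.n_loci_in - self.removed_loci_missing
                - self.removed_loci_maf - self.removed_loci_hwe)


def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value (two-sided, no mid-p correction).

    Sums the probabilities of all heterozygote counts, conditional on the
    observed allele counts, that are no more probable than the observed
    configuration (the standard SNP-HWE enumeration).
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    from scipy.special import gammaln
    n_r = n_rare
    n_c = 2 * n - n_rare
    logp = (gammaln(n + 1)
            - gammaln((n_r - hets) / 2 + 1)
            - gammaln(hets + 1)
            - gammaln((n_c - hets) / 2 + 1)  # common homozygotes
            + hets * np.log(2)
            + gammaln(n_r + 1) + gammaln(n_c + 1) - gammaln(2 * n + 1))
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    d = g.dosages
    out = np.empty(g.n_loci)
    for j in range(g.n_loci):
        col = d[:, j]
        col = col[col != MISSING]
        out[j] = hwe_exact_pvalue(int((col == 1).sum()),
                                  int((col == 2).sum()),
                                  int((col == 0).sum()))
    return out


def apply_qc(g: GenotypeMatrix,
             t: QCThresholds = QCThresholds()) -> tuple[GenotypeMatrix, QCReport]:
    """Filter animals and loci; returns the filtered matrix and a report.

    The filter sequence (animal missingness, locus missingness, MAF, HWE)
    is repeated until it removes nothing: dropping loci changes the
    remaining animals' missing fractions (and vice versa), and the fixed
    point makes the operation idempotent.  An emptied panel is a warning
    (with an empty matrix returned), never an exception, so grid runs can
    log and continue.
    """
    if g.n_loci == 0 or g.n_animals == 0:
        raise QCError("empty genotype matrix")
    rep = QCReport(thresholds=t, n_animals_in=g.n_animals, n_loci_in=g.n_loci)

    changed = True
    while changed and g.n_loci and g.n_animals:
        before = (g.n_animals, g.n_loci)

        miss = g.missing_mask()
        a_keep = np.flatnonzero(miss.mean(axis=1) <= t.animal_missing_max)
        rep.removed_animals_missing += g.n_animals - a_keep.size
        g = g.subset(animals=a_keep)
        if g.n_animals == 0:
            break

        miss = g.missing_mask()
        l_keep = np.flatnonzero(miss.mean(axis=0) <= t.locus_missing_max)
        rep.removed_loci_missing += g.n_loci - l_keep.size
        g = g.subset(loci=l_keep)

        p = g.allele_frequencies()
        maf = np.minimum(p, 1.0 - p)
        l_keep = np.flatnonzero(maf >= t.maf_min)
        rep.removed_loci_maf += g.n_loci - l_keep.size
        g = g.subset(loci=l_keep)

        if g.n_loci:
            pvals = hwe_pvalues(g)
            l_keep = np.flatnonzero(pvals >= t.hwe_p_min)
            rep.removed_loci_hwe += g.n_loci - l_keep.size
            g = g.subset(loci=l_keep)

        changed = (g.n_animals, g.n_loci) != before

    if g.n_loci == 0 or g.n_animals == 0:
        warnings.warn("quality control removed every locus or animal")
    return g, rep
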