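"""Genome map construction for the simulated cattle genome.

The simulated genome mirrors the bovine autosomes: 29 chromosome pairs whose
genetic lengths are proportional to the ARS-UCD1.2 physical assembly sizes,
rescaled to a configurable total map length (default 2715.85 cM).  Biallelic
SNP markers are placed uniformly at random within each chromosome, with the
per-chromosome marker count proportional to chromosome length
(largest-remainder apportionment), and 25 QTL are evenly spaced on every
chromosome (725 genome-wide in the default configuration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Approximate ARS-UCD1.2 autosome physical lengths in Mb, chromosomes 1-29.
# Used only as relative weights; genetic lengths are rescaled to total_cm.
ARS_UCD12_MB = np.array([
    158.53, 136.23, 121.01, 120.83, 120.09, 117.81, 110.68, 113.36,
    105.71, 103.31, 106.98, 87.22, 83.47, 82.40, 85.01, 81.01,
    73.17, 65.82, 63.45, 71.97, 69.86, 60.77, 52.50, 62.32,
    42.35, 51.99, 45.61, 45.94, 51.10,
])

#: Default total genetic map length in centimorgans.
DEFAULT_TOTAL_CM = 2715.85
#: Alternative total map length (whole-genome figure printed alongside
#: the simulation parameter summary).
ALT_TOTAL_CM = 2486.0

#: Marker-panel sizes for the two simulated chip densities.
PANEL_SIZES = {"50k": 58_990, "770k": 777_962}

MARKER = 0
QTL = 1


class GenomeConfigError(ValueError):
    """Raised for invalid genome/panel configurations."""


@dataclass(frozen=True)
class GenomeSpec:
    """Static description of the simulated genome.

    Parameters
    ----------
    n_chromosomes
        Number of autosomes (29 for the cattle genome).
    chr_lengths_cm
        Genetic length of each chromosome in centimorgans.
    n_qtl_per_chr
        Number of evenly spaced QTL per chromosome.
    panel_sizes
        Mapping of density tag -> total marker count across the genome.
    """

    n_chromosomes: int = 29
    chr_lengths_cm: tuple[float, ...] = ()
    n_qtl_per_chr: int = 25
    panel_sizes: dict[str, int] = field(
        default_factory=lambda: dict(PANEL_SIZES))

    def __post_init__(self):
        if not self.chr_lengths_cm:
            object.__setattr__(
                self, "chr_lengths_cm",
                tuple(bovine_chr_lengths(self.n_chromosomes)))
        if len(self.chr_lengths_cm) != self.n_chromosomes:
            raise GenomeConfigError(
                f"{len(self.chr_lengths_cm)} chromosome lengths for "
                f"{self.n_chromosomes} chromosomes")
        if any(l <= 0 for l in self.chr_lengths_cm):
            raise GenomeConfigError("chromosome lengths must be positive")

    @property
    def total_cm(self) -> float:
        return float(sum(self.chr_lengths_cm))


def bovine_chr_lengths(n_chr: int = 29,
                       total_cm: float = DEFAULT_TOTAL_CM) -> np.ndarray:
    """Genetic chromosome lengths proportional to ARS-UCD1.2 physical sizes.

    For ``n_chr`` < 29 the first ``n_chr`` autosomes are used (handy for
    reduced-scale runs); the lengths are rescaled so they sum to a total
    proportional to the included share of the genome.
    """
    if not 1 <= n_chr <= 29:
        raise GenomeConfigError("n_chr must be in 1..29")
    mb = ARS_UCD12_MB[:n_chr]
    return mb * (total_cm / ARS_UCD12_MB.sum())


@dataclass
class MarkerMap:
    """Positions and kinds of all simulated loci, sorted by (chrom, pos).

    ``chrom`` is 1-based; ``pos_cm`` is the genetic position within the
    chromosome; ``kind`` is ``MARKER`` (0) or ``QTL`` (1).
    """

    spec: GenomeSpec
    chrom: np.ndarray          # int16, per locus
    pos_cm: np.ndarray         # float64, per locus
    kind: np.ndarray           # uint8, MARKER/QTL
    locus_ids: np.ndarray      # object/str, per locus

    @property
    def n_loci(self) -> int:
        return self.chrom.size

    @property
    def marker_idx(self) -> np.ndarray:
        return np.flatnonzero(self.kind == MARKER)

    @property
    def qtl_idx(self) -> np.ndarray:
        return np.flatnonzero(self.kind == QTL)

    @property
    def n_markers(self) -> int:
        return int((self.kind == MARKER).sum())

    @property
    def n_qtl(self) -> int:
        return int((self.kind == QTL).sum())

    def recomb_fractions(self) -> np.ndarray:
        """Haldane recombination fraction between each locus and the one
        before it; 0.5 at the first locus of every chromosome (independent
        segregation across chromosomes)."""
        d = np.diff(self.pos_cm, prepend=self.pos_cm[:1])
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        new_chrom = np.empty(self.n_loci, dtype=bool)
        new_chrom[0] = True
        new_chrom[1:] = self.chrom[1:] != self.chrom[:-1]
        r[new_chrom] = 0.5
        return r

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom,
            "locus_id": self.locus_ids,
            "pos_cm": self.pos_cm,
            "kind": np.where(self.kind == QTL, "qtl", "marker"),
        })

    def to_plink_map(self) -> pd.DataFrame:
        """Marker subset in PLINK .map column layout (chrom, id, cM, bp).

        Base-pair positions are derived as round(cM * 1e6), 1-based.
        """
        i = self.marker_idx
        bp = np.maximum(1, np.rint(self.pos_cm[i] * 1e6).astype(np.int64))
        return pd.DataFrame({
            "chrom": self.chrom[i],
            "locus_id": self.locus_ids[i],
            "pos_cm": self.pos_cm[i],
            "pos_bp": bp,
        })


def apportion_largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer counts proportionally to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    if total < 0:
        raise GenomeConfigError("total must be non-negative")
    quota = weights / weights.sum() * total
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def build_genome_map(spec: GenomeSpec, density: str | int,
                     seed: int) -> MarkerMap:
    """Build the marker + QTL map for one chip density.

    ``density`` is a panel tag configured in ``spec.panel_sizes`` (e.g.
    ``"50k"``) or an explicit total marker count.  Marker counts per
    chromosome follow largest-remainder apportionment on chromosome length;
    marker positions are uniform within the chromosome; QTL sit at the
    midpoints of ``n_qtl_per_chr`` equal-length bins.
    """
    if isinstance(density, str):
        try:
            n_markers = spec.panel_sizes[density]
        except KeyError:
            raise GenomeConfigError(f"unknown density tag {density!r}")
    else:
        n_markers = int(density)
    if n_markers < 0:
        raise GenomeConfigError("panel size must be non-negative")
    if 0 < n_markers < spec.n_chromosomes:
        raise GenomeConfigError(
            f"panel of {n_markers} markers cannot cover "
            f"{spec.n_chromosomes} chromosomes")

    rng = np.random.default_rng(seed)
    lengths = np.asarray(spec.chr_lengths_cm)
    per_chr = (apportion_largest_remainder(lengths, n_markers)
               if n_markers else np.zeros(spec.n_chromosomes, dtype=int))

    chroms, poss, kinds = [], [], []
    for c in range(spec.n_chromosomes):
        L = lengths[c]
        m = per_chr[c]
        mpos = np.sort(rng.uniform(0.0, L, size=m))
        nq = spec.n_qtl_per_chr
        qpos = ((np.arange(nq) + 0.5) * (L / nq) if nq else np.empty(0))
        pos = np.concatenate([mpos, qpos])
        kind = np.concatenate([
            np.full(m, MARKER, dtype=np.uint8),
            np.full(spec.n_qtl_per_chr, QTL, dtype=np.uint8),
        ])
        order = np.argsort(pos, kind="stable")
        chroms.append(np.full(pos.size, c + 1, dtype=np.int16))
        poss.append(pos[order])
        kinds.append(kind[order])

    chrom = np.concatenate(chroms)
    pos_cm = np.concatenate(poss)
    kind = np.concatenate(kinds)
    ids = np.empty(chrom.size, dtype=object)
    m_count = q_count = 0
    for i in range(chrom.size):
        if kind[i] == MARKER:
            m_count += 1
            ids[i] = f"snp{m_count}"
        else:
            q_count += 1
            ids[i] = f"qtl{q_count}"
    return MarkerMap(spec=spec, chrom=chrom, pos_cm=pos_cm, kind=kind,
                     locus_ids=ids)
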