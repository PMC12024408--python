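"""Trait architecture: QTL effects, true breeding values, phenotypes.

A single additive trait is simulated.  Absolute QTL effects are drawn from
a gamma distribution (shape 0.4 by default, heavy-tailed so a few QTL carry
large effects), given random signs, and rescaled by one common constant so
that the additive variance in the scaling population,
sum_j 2 p_j (1 - p_j) beta_j^2, equals h2 times the phenotypic variance of
1.0.  The true breeding value of animal k is TBV_k = sum_j beta_j Q_kj with
QTL dosage Q in {0,1,2}, and phenotypes are y = mu + TBV + e with
e ~ N(0, sigma_e2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_GAMMA_SHAPE = 0.4


class TraitError(ValueError):
    pass


@dataclass
class TraitArchitecture:
    """QTL effect vector and variance components of the simulated trait."""

    beta: np.ndarray      # additive effect per QTL copy
    h2: float
    sigma_a2: float
    sigma_e2: float
    mu: float = 0.0
    #: 2p(1-p)beta^2 per QTL in the scaling population
    qtl_variances: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def lambda_ratio(self) -> float:
        """Variance ratio sigma_e2 / sigma_a2 used by the mixed model."""
        if self.sigma_a2 <= 0:
            raise TraitError("lambda undefined for zero additive variance")
        return self.sigma_e2 / self.sigma_a2

    def flag_large_qtl(self, cap: float = 0.02) -> np.ndarray:
        """Indices of QTL whose variance contribution exceeds ``cap``."""
        return np.flatnonzero(self.qtl_variances > cap)


def scale_qtl_effects(raw: np.ndarray, freqs: np.ndarray,
                      sigma_a2_target: float) -> np.ndarray:
    """Rescale raw effects by one common constant c so that
    sum_j 2 p_j (1-p_j) (c raw_j)^2 equals ``sigma_a2_target``."""
    raw = np.asarray(raw, dtype=float)
    p = np.asarray(freqs, dtype=float)
    if sigma_a2_target < 0:
        raise TraitError("target additive variance must be non-negative")
    if sigma_a2_target == 0.0:
        return np.zeros_like(raw)
    het = 2.0 * p * (1.0 - p)
    denom = float(np.sum(het * raw * raw))
    if denom <= 0.0:
        raise TraitError(
            "all QTL monomorphic in the scaling population; "
            "cannot scale effects to the target additive variance")
    return raw * np.sqrt(sigma_a2_target / denom)


def sample_qtl_effects(n_qtl: int, founder_freqs: np.ndarray, h2: float,
                       shape: float = DEFAULT_GAMMA_SHAPE, seed: int = 0,
                       phenotypic_variance: float = 1.0,
                       random_signs: bool = True) -> TraitArchitecture:
    """Draw gamma-distributed QTL effects scaled to the target heritability.

    ``founder_freqs`` are the QTL allele frequencies of the scaling (base)
    population.  After scaling, sum_j 2 p_j (1-p_j) beta_j^2 equals
    ``h2 * phenotypic_variance`` exactly.
    """
    if shape <= 0:
        raise TraitError("gamma shape must be positive")
    if not 0.0 <= h2 < 1.0:
        raise TraitError("h2 must be in [0, 1)")
    p = np.asarray(founder_freqs, dtype=float)
    if p.size != n_qtl:
        raise TraitError("founder_freqs length must equal n_qtl")
    rng = np.random.default_rng(seed)
    raw = rng.gamma(shape, 1.0, size=n_qtl)
    if random_signs:
        raw *= rng.choice([-1.0, 1.0], size=n_qtl)
    het = 2.0 * p * (1.0 - p)
    target = h2 * phenotypic_variance
    beta = scale_qtl_effects(raw, p, target)
    return TraitArchitecture(
        beta=beta,
        h2=h2,
        sigma_a2=target,
        sigma_e2=phenotypic_variance - target,
        qtl_variances=het * beta * beta,
    )


def compute_tbv(qtl_dosages: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """True breeding values: TBV_k = sum_j beta_j Q_kj."""
    Q = np.asarray(qtl_dosages)
    if Q.ndim != 2 or Q.shape[1] != arch.beta.size:
        raise TraitError(
            f"dosage matrix with {Q.shape} does not match "
            f"{arch.beta.size} QTL effects")
    return Q.astype(float) @ arch.beta


def simulate_phenotypes(tbv: np.ndarray, arch: TraitArchitecture, seed: int,
                        ids: np.ndarray | None = None,
                        generation: np.ndarray | None = None,
                        sex: np.ndarray | None = None) -> pd.DataFrame:
    """Phenotypes y = mu + TBV + e, e ~ N(0, sigma_e2).

    Returns a table with columns animal_id, tbv, phenotype, generation, sex.
    """
    if arch.sigma_e2 < 0:
        raise TraitError("residual variance must be non-negative")
    tbv = np.asarray(tbv, dtype=float)
    rng = np.random.default_rng(seed)
    e = (rng.normal(0.0, np.sqrt(arch.sigma_e2), size=tbv.size)
         if arch.sigma_e2 > 0 else np.zeros(tbv.size))
    n = tbv.size
    return pd.DataFrame({
        "animal_id": ids if ids is not None else np.arange(1, n + 1),
        "tbv": tbv,
        "phenotype": arch.mu + tbv + e,
        "generation": generation if generation is not None else np.zeros(n, int),
        "sex": sex if sex is not None else np.zeros(n, np.uint8),
    })


def export_phenotypes(table: pd.DataFrame, path, sire=None, dam=None,
                      include_tbv: bool = False) -> None:
    """Write a whitespace-delimited phenotype/pedigree file.

    The TBV column is withheld unless explicitly requested: true breeding
    values must never reach the estimators.
    """
    out = table.copy()
    if not include_tbv:
        out = out.drop(columns=["tbv"], errors="ignore")
    out.to_csv(path, sep=" ", index=False)
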