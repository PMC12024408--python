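"""Mixed-model equations for PBLUP, GBLUP and SNP-BLUP (ridge) fits.

All three estimators solve Henderson-type block systems

    [X'X   X'Z     ] [b]   [X'y]
    [Z'X   Z'Z + lK] [u] = [Z'y]

with K = A^-1 (pedigree), G^-1 (genomic) or W^-1 (diagonal SNP prior) and
variance ratio l (lambda) = sigma_e2 / sigma_u2.  Systems are solved either
densely (small instances, oracle checks) or by Jacobi-preconditioned
conjugate gradients; with lambda > 0 and a full-column-rank fixed-effect
design the coefficient matrix is symmetric positive definite, so CG applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .kinship import RelationshipMatrix, a_inverse, stabilize
from .pedigree import Pedigree


class BlupError(ValueError):
    pass


@dataclass
class SolverDiagnostics:
    method: str
    iterations: int
    residual_norm: float
    converged: bool
    n_equations: int


@dataclass
class MMESolution:
    """Fixed-effect estimates and random-effect predictions."""

    b_hat: np.ndarray
    u_hat: np.ndarray            # EBVs / GEBVs / SNP effects
    ids: np.ndarray | None
    diagnostics: SolverDiagnostics
    extras: dict = field(default_factory=dict)

    def predictions(self, ids) -> np.ndarray:
        """Random-effect predictions for the requested animal IDs."""
        pos = {int(a): i for i, a in enumerate(self.ids)}
        return self.u_hat[[pos[int(a)] for a in np.atleast_1d(ids)]]


def _drop_dependent_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Keep a full-column-rank subset of X (QR with column pivoting)."""
    if X.shape[1] == 1:
        return X, np.array([0])
    from scipy.linalg import qr
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    if rank < X.shape[1]:
        warnings.warn(f"dropped {X.shape[1] - rank} dependent fixed-effect "
                      "column(s)")
    return X[:, keep], keep


def solve_mme(C, rhs: np.ndarray, method: str = "cg",
              rtol: float = 1e-8,
              maxiter: int | None = None) -> tuple[np.ndarray, SolverDiagnostics]:
    """Solve the assembled MME ``C x = rhs``.

    method="cg" uses Jacobi-preconditioned conjugate gradients (relative
    residual ``rtol``); method="direct" densifies and uses a direct solve.
    """
    n = rhs.size
    if method == "direct":
        Cd = C.toarray() if sp.issparse(C) else np.asarray(C)
        x = np.linalg.solve(Cd, rhs)
        res = float(np.linalg.norm(Cd @ x - rhs) / np.linalg.norm(rhs))
        ok = res < 1e-6
        if not ok:
            warnings.warn(
                f"direct solve left relative residual {res:.2e}; the "
                "coefficient matrix is (near-)singular — for a GRM built "
                "with observed allele frequencies, stabilize with blend > 0")
        return x, SolverDiagnostics("direct", 1, res, ok, n)
    if method != "cg":
        raise BlupError(f"unknown solver {method!r}")
    if maxiter is None:
        maxiter = max(1000, 10 * n)
    diag = C.diagonal() if sp.issparse(C) else np.diag(C).copy()
    diag = np.where(diag > 0, diag, 1.0)
    M = spla.LinearOperator((n, n), matvec=lambda v: v / diag)
    it = 0

    def count(_):
        nonlocal it
        it += 1

    x, info = spla.cg(C, rhs, rtol=rtol, atol=0.0, maxiter=maxiter, M=M,
                      callback=count)
    res = float(np.linalg.norm((C @ x) - rhs) / np.linalg.norm(rhs))
    converged = info == 0 and res <= rtol * 10
    if not converged:
        warnings.warn(
            f"conjugate gradient did not converge in {it} iterations "
            f"(relative residual {res:.2e})")
    return x, SolverDiagnostics("cg", it, res, converged, n)


def _assemble(X: np.ndarray, Z: sp.spmatrix, K, lam: float,
              y: np.ndarray) -> tuple[sp.spmatrix, np.ndarray, np.ndarray]:
    X, keep = _drop_dependent_columns(np.asarray(X, dtype=float))
    Xs = sp.csr_matrix(X)
    ZtZ = (Z.T @ Z).tocsr()
    Ksp = K if sp.issparse(K) else sp.csr_matrix(K)
    C = sp.bmat([
        [Xs.T @ Xs, Xs.T @ Z],
        [Z.T @ Xs, ZtZ + lam * Ksp],
    ], format="csr")
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    return C, rhs, keep


def _solve_animal_model(y: np.ndarray, X: np.ndarray, Z: sp.spmatrix,
                        K, lam: float, ids: np.ndarray,
                        method: str, rtol: float,
                        maxiter: int | None) -> MMESolution:
    if lam <= 0:
        raise BlupError("variance ratio lambda must be positive")
    y = np.asarray(y, dtype=float)
    C, rhs, _ = _assemble(X, Z, K, lam, y)
    nf = rhs.size - Z.shape[1]
    x, diag = solve_mme(C, rhs, method=method, rtol=rtol, maxiter=maxiter)
    return MMESolution(b_hat=x[:nf], u_hat=x[nf:], ids=ids, diagnostics=diag)


def incidence_matrix(record_ids, all_ids) -> sp.csr_matrix:
    """Z mapping records to animal effects (n_records x n_animals)."""
    pos = {int(a): i for i, a in enumerate(all_ids)}
    rows = np.arange(len(record_ids))
    cols = np.array([pos[int(a)] for a in record_ids])
    data = np.ones(len(record_ids))
    return sp.csr_matrix((data, (rows, cols)),
                         shape=(len(record_ids), len(all_ids)))


def solve_pblup(y: np.ndarray, record_ids: np.ndarray, ped: Pedigree,
                lam: float, X: np.ndarray | None = None,
                method: str = "cg", rtol: float = 1e-8,
                maxiter: int | None = None,
                ainv: RelationshipMatrix | None = None) -> MMESolution:
    """Pedigree BLUP: EBVs for every pedigree animal from the records in
    ``y`` (one row per record, attached to ``record_ids``).

    Animals without records receive EBVs through their pedigree ties.
    """
    if ainv is None:
        ainv = a_inverse(ped)
    if X is None:
        X = np.ones((len(y), 1))
    Z = incidence_matrix(record_ids, ped.ids)
    return _solve_animal_model(y, X, Z, ainv.values, lam, ped.ids,
                               method, rtol, maxiter)


def solve_gblup(y: np.ndarray, record_ids: np.ndarray,
                G: RelationshipMatrix | np.ndarray,
                lam: float, ids: np.ndarray | None = None,
                X: np.ndarray | None = None, blend: float = 0.01,
                method: str = "cg", rtol: float = 1e-8,
                maxiter: int | None = None) -> MMESolution:
    """Genomic BLUP: GEBVs for every genotyped animal in ``G``.

    ``G`` is stabilized as (1-blend) G + blend I before inversion; pass
    blend=0 for an already positive-definite matrix.
    """
    if isinstance(G, RelationshipMatrix):
        ids = G.ids if ids is None else ids
        G = G.toarray()
    if ids is None:
        raise BlupError("animal IDs required with a raw G array")
    Gs = stabilize(G, blend)
    try:
        Ginv = np.linalg.inv(Gs)
    except np.linalg.LinAlgError as e:
        raise BlupError(f"G is singular after stabilization: {e}") from e
    if X is None:
        X = np.ones((len(y), 1))
    Z = incidence_matrix(record_ids, ids)
    return _solve_animal_model(y, X, Z, Ginv, lam, np.asarray(ids),
                               method, rtol, maxiter)


def standardize_genotypes(M: np.ndarray, freqs: np.ndarray | None = None
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center dosages by 2p and scale columns by sqrt(2p(1-p)).

    Returns (Zs, p, keep) where ``keep`` flags segregating loci; columns of
    monomorphic loci are returned as zeros.
    """
    M = np.asarray(M, dtype=float)
    p = M.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, float)
    het = 2.0 * p * (1.0 - p)
    keep = het > 0
    Zs = np.zeros_like(M)
    Zs[:, keep] = (M[:, keep] - 2.0 * p[keep]) / np.sqrt(het[keep])
    return Zs, p, keep


def snp_blup(y: np.ndarray, Zs: np.ndarray, lam: float,
             weights: np.ndarray | None = None,
             X: np.ndarray | None = None,
             method: str = "direct", rtol: float = 1e-8,
             maxiter: int | None = None) -> MMESolution:
    """Ridge (SNP-BLUP) fit of marker effects on a standardized design.

    Model: y = Xb + Zs a + e with a ~ N(0, W sigma_a2) diagonal, R = I,
    and lam = sigma_e2 / sigma_a2 so the penalty is lam * W^-1.  Markers
    with zero weight or a zero-variance column get a_hat = 0 and are
    excluded from the W^-1 inversion.
    """
    y = np.asarray(y, dtype=float)
    Zs = np.asarray(Zs, dtype=float)
    m = Zs.shape[1]
    w = np.ones(m) if weights is None else np.asarray(weights, float)
    if w.size != m:
        raise BlupError("weight vector length mismatch")
    if np.any(w < 0):
        raise BlupError("weights must be non-negative")
    colvar = (Zs ** 2).sum(axis=0)
    active = (w > 0) & (colvar > 0)
    if (w > 0).sum() and not (colvar > 0)[w > 0].all():
        warnings.warn("zero-variance marker column(s) excluded from the fit")
    Za = Zs[:, active]
    if X is None:
        X = np.ones((len(y), 1))
    X, _ = _drop_dependent_columns(np.asarray(X, dtype=float))
    nf = X.shape[1]
    ma = Za.shape[1]
    if lam < 0:
        raise BlupError("lambda must be non-negative")
    pen = np.diag(lam / w[active]) if ma else np.zeros((0, 0))
    C = np.block([
        [X.T @ X, X.T @ Za],
        [Za.T @ X, Za.T @ Za + pen],
    ])
    rhs = np.concatenate([X.T @ y, Za.T @ y])
    if lam == 0 and ma >= len(y):
        warnings.warn("unpenalized system may be singular; using lstsq")
        x, *_ = np.linalg.lstsq(C, rhs, rcond=None)
        diag = SolverDiagnostics("lstsq", 1, 0.0, True, rhs.size)
    else:
        x, diag = solve_mme(C, rhs, method=method, rtol=rtol, maxiter=maxiter)
    alpha = np.zeros(m)
    alpha[active] = x[nf:]
    return MMESolution(b_hat=x[:nf], u_hat=alpha, ids=None, diagnostics=diag,
                       extras={"active": active})
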