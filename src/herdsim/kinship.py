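"""Relationship matrices: pedigree NRM (A, A-inverse) and genomic GRM.

The numerator relationship matrix A is built by the tabular (recursive)
method; its inverse is assembled directly from Henderson's rules with
inbreeding coefficients from the Meuwissen-Luo algorithm, so A never has
to be inverted explicitly.  The genomic relationship matrix follows
VanRaden's first method, G = ZZ' / sum_i 2 p_i (1 - p_i) with Z the
column-centered dosage matrix; an uncentered variant (G = MM' over the raw
0/1/2 dosages) is available behind a flag, and a SNP-weighted form
G_w = Z diag(W) Z' with either the VanRaden or the standardized-design
normalisation supports weighted GBLUP.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .pedigree import Pedigree


class KinshipError(ValueError):
    pass


@dataclass
class RelationshipMatrix:
    """Dense or sparse relationship matrix with its animal index."""

    kind: str                    # "A", "A_inverse", "G", "G_weighted"
    ids: np.ndarray
    values: np.ndarray | sp.spmatrix

    def toarray(self) -> np.ndarray:
        if sp.issparse(self.values):
            return self.values.toarray()
        return self.values


def numerator_relationship(ped: Pedigree) -> RelationshipMatrix:
    """Tabular-method A: a_ii = 1 + a(s,d)/2, a_ij = (a(j,s) + a(j,d))/2."""
    s, d = ped.parent_indices()
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
    return RelationshipMatrix(kind="A", ids=ped.ids, values=A)


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen-Luo algorithm.

    Computes a_ii = sum over ancestors j of L_ij^2 D_j without forming A,
    tracing each animal's ancestor paths with a max-heap.
    """
    s, d = ped.parent_indices()
    n = ped.n
    F = np.zeros(n)
    D = np.zeros(n)
    for i in range(n):
        si, di = s[i], d[i]
        fs = F[si] if si >= 0 else 0.0
        fd = F[di] if di >= 0 else 0.0
        if si >= 0 and di >= 0:
            D[i] = 0.5 - 0.25 * (fs + fd)
        elif si >= 0 or di >= 0:
            D[i] = 0.75 - 0.25 * (fs + fd)
        else:
            D[i] = 1.0
        # founders and animals with an unknown parent are non-inbred here
        if si < 0 or di < 0:
            F[i] = 0.0
            continue
        L = {i: 1.0}
        heap = [-i]
        in_heap = {i}
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            in_heap.discard(j)
            lj = L.pop(j)
            if lj == 0.0:
                continue
            for pj in (s[j], d[j]):
                if pj >= 0:
                    L[pj] = L.get(pj, 0.0) + 0.5 * lj
                    if pj not in in_heap:
                        heapq.heappush(heap, -pj)
                        in_heap.add(pj)
            aii += lj * lj * D[j]
        F[i] = aii - 1.0
    return F


def a_inverse(ped: Pedigree) -> RelationshipMatrix:
    """A^-1 assembled directly by Henderson's rules with Meuwissen-Luo
    inbreeding in the Mendelian-sampling variances.  Sparse output."""
    s, d = ped.parent_indices()
    n = ped.n
    F = inbreeding_coefficients(ped)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        si, di = s[i], d[i]
        fs = F[si] if si >= 0 else 0.0
        fd = F[di] if di >= 0 else 0.0
        if si >= 0 and di >= 0:
            dms = 0.5 - 0.25 * (fs + fd)
        elif si >= 0 or di >= 0:
            dms = 0.75 - 0.25 * (fs + fd)
        else:
            dms = 1.0
        alpha = 1.0 / dms
        add(i, i, alpha)
        for p in (si, di):
            if p >= 0:
                add(i, p, -alpha / 2.0)
                add(p, i, -alpha / 2.0)
        for p in (si, di):
            for q in (si, di):
                if p >= 0 and q >= 0:
                    add(p, q, alpha / 4.0)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipMatrix(kind="A_inverse", ids=ped.ids, values=Ainv)


def _prepare_dosages(dosages: np.ndarray,
                     freqs: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    M = np.asarray(dosages, dtype=float)
    if M.ndim != 2:
        raise KinshipError("dosage matrix must be 2-D (animals x loci)")
    p = M.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, float)
    if p.size != M.shape[1]:
        raise KinshipError("frequency vector length mismatch")
    return M, p


def grm(dosages: np.ndarray, freqs: np.ndarray | None = None,
        ids: np.ndarray | None = None,
        centered: bool = True) -> RelationshipMatrix:
    """VanRaden method-1 GRM (default) or the raw uncentered MM' form.

    Frequencies default to those observed in ``dosages``.
    """
    M, p = _prepare_dosages(dosages, freqs)
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0.0:
        raise KinshipError(
            "all loci monomorphic (sum 2p(1-p) = 0); supply a segregating "
            "panel or explicit frequencies")
    Z = M - 2.0 * p if centered else M
    G = (Z @ Z.T) / denom
    if ids is None:
        ids = np.arange(1, M.shape[0] + 1)
    return RelationshipMatrix(kind="G", ids=np.asarray(ids), values=G)


def weighted_grm(dosages: np.ndarray, weights: np.ndarray,
                 freqs: np.ndarray | None = None,
                 ids: np.ndarray | None = None,
                 scaling: str = "vanraden") -> RelationshipMatrix:
    """SNP-weighted GRM.

    scaling="vanraden": G_w = Z diag(W) Z' / sum_i 2 p_i (1-p_i) W_i with
    Z = M - 2p (reduces to the unweighted GRM at W = 1).
    scaling="standardized": G_w = Zs diag(W) Zs' / sum_i W_i with Zs the
    per-locus standardized design (Z columns divided by sqrt(2p(1-p)));
    this is the form under which weighted GBLUP is exactly equivalent to
    SNP-BLUP with prior variances proportional to W.
    """
    M, p = _prepare_dosages(dosages, freqs)
    w = np.asarray(weights, dtype=float)
    if w.size != M.shape[1]:
        raise KinshipError("weight vector length mismatch")
    if np.any(w < 0):
        raise KinshipError("weights must be non-negative")
    het = 2.0 * p * (1.0 - p)
    Z = M - 2.0 * p
    if scaling == "vanraden":
        denom = float(np.sum(het * w))
        if denom <= 0.0:
            raise KinshipError("zero total weighted heterozygosity")
        G = (Z * w) @ Z.T / denom
    elif scaling == "standardized":
        keep = het > 0
        denom = float(w[keep].sum())
        if denom <= 0.0:
            raise KinshipError("zero total weight on segregating loci")
        Zs = Z[:, keep] / np.sqrt(het[keep])
        G = (Zs * w[keep]) @ Zs.T / denom
    else:
        raise KinshipError(f"unknown scaling {scaling!r}")
    if ids is None:
        ids = np.arange(1, M.shape[0] + 1)
    return RelationshipMatrix(kind="G_weighted", ids=np.asarray(ids), values=G)


def stabilize(G: np.ndarray, blend: float = 0.01) -> np.ndarray:
    """Blend G with the identity, (1-blend) G + blend I, to guarantee an
    invertible matrix for the mixed-model equations."""
    if not 0.0 <= blend < 1.0:
        raise KinshipError("blend must be in [0, 1)")
    if blend == 0.0:
        return np.asarray(G, dtype=float)
    G = np.asarray(G, dtype=float)
    return (1.0 - blend) * G + blend * np.eye(G.shape[0])
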