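"""Mixed-model solvers: shrinkage limits, oracle solves, equivalences."""

import numpy as np
import pytest
import scipy.sparse as sp

from herdsim.blup import (incidence_matrix, snp_blup, solve_gblup, solve_mme,
                          solve_pblup, standardize_genotypes)
from herdsim.kinship import a_inverse, numerator_relationship, weighted_grm
from tests.conftest import random_pedigree


def simulate_records(ped, h2, seed, frac_recorded=1.0):
    """Phenotypes from a polygenic model on a pedigree (for solver tests)."""
    rng = np.random.default_rng(seed)
    n = ped.n
    s, d = ped.parent_indices()
    u = np.zeros(n)
    for i in range(n):
        mu = 0.0
        if s[i] >= 0:
            mu += u[s[i]] / 2
        if d[i] >= 0:
            mu += u[d[i]] / 2
        ms_var = h2 * (1.0 if s[i] < 0 and d[i] < 0 else 0.5)
        u[i] = mu + rng.normal(0, np.sqrt(ms_var))
    rec = np.flatnonzero(rng.random(n) < frac_recorded)
    y = u[rec] + rng.normal(0, np.sqrt(1 - h2), size=rec.size)
    return y, ped.ids[rec], u


class TestPBLUP:
    def test_single_record_mean_absorbs_everything(self):
        ped = random_pedigree(1, seed=1)
        sol = solve_pblup(np.array([3.2]), ped.ids, ped, lam=1.0)
        assert abs(sol.u_hat[0]) < 1e-10
        assert sol.b_hat[0] == pytest.approx(3.2)

    def test_extreme_lambda_shrinks_to_zero(self):
        ped = random_pedigree(30, seed=2)
        y, ids, _ = simulate_records(ped, 0.5, seed=3)
        sol = solve_pblup(y, ids, ped, lam=1e12)
        assert np.abs(sol.u_hat).max() < 1e-6

    def test_cg_matches_direct_solve(self):
        ped = random_pedigree(20, seed=4)
        y, ids, _ = simulate_records(ped, 0.5, seed=5)
        cg = solve_pblup(y, ids, ped, lam=1.0, method="cg")
        direct = solve_pblup(y, ids, ped, lam=1.0, method="direct")
        assert np.abs(cg.u_hat - direct.u_hat).max() < 1e-6
        assert cg.diagnostics.converged

    def test_translation_invariance_of_ebvs(self):
        ped = random_pedigree(40, seed=6)
        y, ids, _ = simulate_records(ped, 0.5, seed=7)
        a = solve_pblup(y, ids, ped, lam=1.0, method="direct")
        b = solve_pblup(y + 100.0, ids, ped, lam=1.0, method="direct")
        assert np.abs(a.u_hat - b.u_hat).max() < 1e-8
        assert b.b_hat[0] - a.b_hat[0] == pytest.approx(100.0, abs=1e-8)

    def test_unrecorded_terminal_offspring_gets_parent_average(self):
        ped = random_pedigree(25, seed=8)
        # last animal: no record, no descendants -> EBV = parent average
        y, ids, _ = simulate_records(ped, 0.5, seed=9)
        keep = ids != ped.ids[-1]
        sol = solve_pblup(y[keep], ids[keep], ped, lam=1.0)
        i = ped.n - 1
        s, d = ped.parent_indices()
        expected = 0.0
        if s[i] >= 0:
            expected += sol.u_hat[s[i]] / 2
        if d[i] >= 0:
            expected += sol.u_hat[d[i]] / 2
        assert sol.u_hat[i] == pytest.approx(expected, abs=1e-6)


class TestGBLUP:
    def test_g_equal_a_reproduces_pblup(self):
        ped = random_pedigree(35, seed=10)
        y, ids, _ = simulate_records(ped, 0.5, seed=11)
        A = numerator_relationship(ped)
        gsol = solve_gblup(y, ids, A.toarray(), lam=1.0, ids=ped.ids,
                           blend=0.0, method="direct")
        psol = solve_pblup(y, ids, ped, lam=1.0, method="direct")
        assert np.abs(gsol.u_hat - psol.u_hat).max() < 1e-8

    def test_duplicate_genotypes_equal_gebvs(self):
        rng = np.random.default_rng(12)
        M = rng.binomial(2, 0.5, size=(20, 60))
        M[1] = M[0]
        from herdsim.kinship import grm
        ids = np.arange(1, 21)
        y = rng.normal(size=20)
        y[1] = y[0]
        sol = solve_gblup(y, ids, grm(M, ids=ids), lam=1.0)
        assert sol.u_hat[0] == pytest.approx(sol.u_hat[1], abs=1e-6)

    def test_gblup_equals_snp_blup_backsolve(self):
        """GEBV from G = Zs Zs'/m equals Zs alpha_hat with lam_snp = m lam."""
        rng = np.random.default_rng(13)
        n, m = 30, 100
        p_true = rng.uniform(0.2, 0.8, m)
        M = rng.binomial(2, p_true, size=(n, m))
        # external frequencies: with observed frequencies the centered
        # scores sum to zero and G = Zs Zs'/m is exactly singular
        Zs, p, keep = standardize_genotypes(M, freqs=p_true)
        ids = np.arange(1, n + 1)
        y = rng.normal(size=n)
        lam_g = 1.0
        G = weighted_grm(M, np.ones(m), freqs=p_true,
                         scaling="standardized")
        gsol = solve_gblup(y, ids, G, lam=lam_g, blend=0.0, method="direct")
        ssol = snp_blup(y, Zs, lam=lam_g * keep.sum())
        assert np.abs(gsol.u_hat - Zs @ ssol.u_hat).max() < 1e-6


class TestSNPBLUP:
    def test_ols_limit_single_marker(self):
        rng = np.random.default_rng(14)
        z = rng.normal(size=12)
        z -= z.mean()
        y = 0.7 * z + 0.1
        sol = snp_blup(y, z[:, None], lam=0.0)
        beta = (z @ (y - y.mean())) / (z @ z)
        assert sol.u_hat[0] == pytest.approx(beta, abs=1e-8)

    def test_shrinkage_monotone_in_lambda(self):
        rng = np.random.default_rng(15)
        Z = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        norms = [np.abs(snp_blup(y, Z, lam=lam).u_hat).mean()
                 for lam in (0.1, 1.0, 10.0, 1e3, 1e6)]
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-4

    def test_hand_assembled_normal_equations(self):
        rng = np.random.default_rng(16)
        Z = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        lam = 2.5
        w = np.array([1.0, 0.5, 2.0])
        X = np.ones((10, 1))
        C = np.block([
            [X.T @ X, X.T @ Z],
            [Z.T @ X, Z.T @ Z + lam * np.diag(1 / w)],
        ])
        rhs = np.concatenate([X.T @ y, Z.T @ y])
        expected = np.linalg.solve(C, rhs)
        sol = snp_blup(y, Z, lam=lam, weights=w)
        assert np.allclose(sol.b_hat, expected[:1])
        assert np.allclose(sol.u_hat, expected[1:])

    def test_zero_weight_markers_get_zero_effect(self):
        rng = np.random.default_rng(17)
        Z = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        w = np.array([1.0, 0.0, 1.0, 1.0, 0.0])
        sol = snp_blup(y, Z, lam=1.0, weights=w)
        assert sol.u_hat[1] == 0.0 and sol.u_hat[4] == 0.0

    def test_zero_variance_column_warns_and_is_excluded(self):
        rng = np.random.default_rng(18)
        Z = rng.normal(size=(15, 4))
        Z[:, 2] = 0.0
        y = rng.normal(size=15)
        with pytest.warns(UserWarning, match="zero-variance"):
            sol = snp_blup(y, Z, lam=1.0)
        assert sol.u_hat[2] == 0.0


class TestSolver:
    @pytest.mark.parametrize("n_eq,seed", [(100, 19), (300, 20)])
    def test_cg_vs_dense_direct_on_random_spd(self, n_eq, seed):
        rng = np.random.default_rng(seed)
        B = rng.normal(size=(n_eq, n_eq))
        C = B @ B.T + n_eq * np.eye(n_eq)
        rhs = rng.normal(size=n_eq)
        x_cg, diag = solve_mme(sp.csr_matrix(C), rhs, method="cg")
        x_direct = np.linalg.solve(C, rhs)
        assert np.abs(x_cg - x_direct).max() < 1e-6
        assert diag.converged

    def test_nonconvergence_is_reported_not_silent(self):
        rng = np.random.default_rng(21)
        B = rng.normal(size=(50, 50))
        C = B @ B.T + 1e-9 * np.eye(50)  # terribly conditioned
        rhs = rng.normal(size=50)
        with pytest.warns(UserWarning, match="did not converge"):
            _, diag = solve_mme(sp.csr_matrix(C), rhs, method="cg",
                                maxiter=3)
        assert not diag.converged

    def test_incidence_matrix_maps_records(self):
        Z = incidence_matrix([3, 1], [1, 2, 3])
        assert np.array_equal(Z.toarray(),
                              [[0, 0, 1], [1, 0, 0]])
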