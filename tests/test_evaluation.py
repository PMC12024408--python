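"""Scenario orchestration: splits, accuracy, grids, printed-table summaries."""

import numpy as np
import pandas as pd
import pytest

from herdsim.evaluation import (EvaluationError, ScenarioConfig, accuracy,
                                density_gain, grid_configs, method_gain,
                                run_grid, run_scenario,
                                split_reference_validation, summarize_grid)
from herdsim.printed import printed_accuracies


def candidate_table(n9=60, n10=80):
    ids = np.arange(1, n9 + n10 + 1)
    return pd.DataFrame({
        "animal_id": ids,
        "generation": np.r_[np.full(n9, 9), np.full(n10, 10)],
        "phenotype": np.zeros(ids.size),
        "tbv": np.zeros(ids.size),
    })


class TestSplit:
    def test_reference_is_exact_complement(self):
        cand = candidate_table()
        ref, val = split_reference_validation(cand, rp_size=120,
                                              n_validation=20, seed=1)
        assert len(ref) == 120 and len(val) == 20
        assert not set(ref) & set(val)
        assert set(ref) | set(val) == set(cand["animal_id"])

    def test_validation_only_from_last_generation(self):
        cand = candidate_table()
        _, val = split_reference_validation(cand, 50, 30, seed=2)
        gen = cand.set_index("animal_id")["generation"]
        assert (gen.loc[val] == 10).all()

    def test_same_seed_same_split(self):
        cand = candidate_table()
        a = split_reference_validation(cand, 50, 30, seed=3)
        b = split_reference_validation(cand, 50, 30, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_nested_reference_chain_with_common_seed(self):
        cand = candidate_table()
        sets = [set(split_reference_validation(cand, rp, 20, seed=4)[0])
                for rp in (30, 60, 90, 120)]
        for small, big in zip(sets, sets[1:]):
            assert small < big

    def test_infeasible_sizes_report_shortfall(self):
        cand = candidate_table()
        with pytest.raises(EvaluationError, match="short by"):
            split_reference_validation(cand, 200, 20, seed=5)
        with pytest.raises(EvaluationError, match="validation"):
            split_reference_validation(cand, 10, 100, seed=5)


class TestAccuracy:
    def test_perfect_and_sign_flipped(self):
        t = np.array([0.1, 0.5, -0.2, 1.0])
        assert accuracy(t, t) == pytest.approx(1.0)
        assert accuracy(t, -t) == pytest.approx(-1.0)

    def test_hand_pearson(self):
        r = accuracy(np.array([1, 2, 3, 4]), np.array([1, 2, 3, 5]))
        assert r == pytest.approx(0.9827076, abs=1e-6)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(EvaluationError):
            accuracy(np.ones(5), np.arange(5))
        with pytest.raises(EvaluationError):
            accuracy(np.arange(4), np.arange(3))
        with pytest.raises(EvaluationError):
            accuracy(np.arange(2), np.arange(2))


class TestScenario:
    def test_validation_phenotypes_never_enter_the_fit(self, small_dataset):
        """Corrupting masked phenotypes must not change any prediction."""
        import copy
        cfg = ScenarioConfig("A", 0.5, small_dataset.design.density,
                             rp_size=100, method="GBLUP", replicate_seed=6,
                             n_validation=50)
        base = run_scenario(cfg, small_dataset)
        tainted = copy.copy(small_dataset)
        tainted.phenotypes = small_dataset.phenotypes.copy()
        _, val = split_reference_validation(
            tainted.phenotypes, cfg.rp_size, cfg.n_validation,
            cfg.replicate_seed)
        mask = tainted.phenotypes["animal_id"].isin(val)
        tainted.phenotypes.loc[mask, "phenotype"] = 1e9
        again = run_scenario(cfg, tainted)
        assert again.accuracy == pytest.approx(base.accuracy, abs=1e-12)

    def test_methods_run_and_report_sizes(self, small_dataset):
        for method in ("PBLUP", "GBLUP", "wGBLUP"):
            cfg = ScenarioConfig("A", 0.5, small_dataset.design.density,
                                 rp_size=100, method=method,
                                 replicate_seed=7, n_validation=50)
            res = run_scenario(cfg, small_dataset)
            assert res.n_reference == 100 and res.n_validation == 50
            assert -1.0 <= res.accuracy <= 1.0

    def test_unknown_method_rejected(self):
        with pytest.raises(EvaluationError):
            ScenarioConfig("A", 0.5, "50k", 100, "BayesR", 1)

    def test_noiseless_gblup_with_causal_markers_is_near_perfect(self):
        """sigma_e ~ 0 and markers containing the causal loci: accuracy ~ 1."""
        rng = np.random.default_rng(8)
        n, m, n_train = 600, 120, 500
        p = rng.uniform(0.2, 0.8, m)
        M = rng.binomial(2, p, size=(n, m))
        beta = np.zeros(m)
        beta[rng.choice(m, 20, replace=False)] = rng.normal(size=20)
        g = (M - 2 * p) @ beta
        from herdsim.blup import solve_gblup
        from herdsim.kinship import grm
        ids = np.arange(1, n + 1)
        # n_train > m: marker effects identifiable, so the unpenalized
        # limit recovers the genetic values of unphenotyped animals
        sol = solve_gblup(g[:n_train], ids[:n_train], grm(M, ids=ids),
                          lam=1e-6, blend=1e-10)
        assert accuracy(g[n_train:], sol.u_hat[n_train:]) > 0.97


class TestGrid:
    def test_one_cell_two_replicates(self, small_dataset):
        cfgs = grid_configs(["A"], [0.5], [small_dataset.design.density],
                            [100], methods=("GBLUP",),
                            replicate_seeds=(11, 12), n_validation=50)
        res = run_grid(cfgs, lambda cfg: small_dataset)
        assert len(res) == 2
        summary = summarize_grid(res)
        assert len(summary) == 1
        assert summary.loc[0, "count"] == 2

    def test_resumability(self, small_dataset, tmp_path):
        cache = tmp_path / "grid.csv"
        cfgs = grid_configs(["A"], [0.5], [small_dataset.design.density],
                            [100], methods=("GBLUP", "PBLUP"),
                            replicate_seeds=(13,), n_validation=50)
        first = run_grid(cfgs, lambda cfg: small_dataset, cache_path=cache)
        calls = []

        def provider(cfg):
            calls.append(cfg)
            return small_dataset

        second = run_grid(cfgs, provider, cache_path=cache)
        assert not calls  # everything served from the cache
        pd.testing.assert_frame_equal(
            first.sort_values("key").reset_index(drop=True),
            second.sort_values("key").reset_index(drop=True),
            check_dtype=False)

    def test_scaled_paper_grid_row_arithmetic(self):
        cfgs = grid_configs(["A"], [0.3, 0.5, 0.7], ["50k", "770k"],
                            [500, 800, 1200, 1500],
                            replicate_seeds=(1, 2, 3, 4))
        assert len(cfgs) == 288  # 72 cells x 4 replicates


class TestPrintedSummaries:
    def test_density_gain_quoted_pblup_case(self):
        table = printed_accuracies("text")
        gain = density_gain(table, "A", 8000, 0.5, "PBLUP")
        assert round(gain, 2) == 4.29

    def test_equal_accuracies_give_zero(self):
        table = pd.DataFrame({
            "breed": ["A", "A"], "rp_size": [100, 100], "h2": [0.5, 0.5],
            "density": ["50k", "770k"], "method": ["GBLUP", "GBLUP"],
            "accuracy": [0.7, 0.7]})
        assert density_gain(table, "A", 100, 0.5, "GBLUP") == 0.0

    def test_missing_cell_raises(self):
        table = printed_accuracies("text")
        with pytest.raises(EvaluationError):
            density_gain(table, "A", 9999, 0.5, "PBLUP")

    def test_method_gain_on_table2(self):
        table = printed_accuracies("table2")
        gain = method_gain(table, "A", 5000, 0.3, "50k", "GBLUP", "PBLUP")
        assert gain == pytest.approx((0.6085367 - 0.5609333) * 100)

    def test_table2_is_complete(self):
        table = printed_accuracies("table2")
        assert len(table) == 72
        assert table["accuracy"].between(0.5, 0.9).all()
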