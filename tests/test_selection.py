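"""Truncation, index, fitness matrix and GA mate allocation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import safbreed as sb
from safbreed.selection import plan_objective


def _grm(values, n):
    G = np.asarray(values, dtype=float)
    return sb.GRMatrix(G, np.empty(0), list(range(n)))


class TestTruncation:
    def test_picks_largest(self):
        assert sb.select_truncation([3.0, 1.0, 2.0], ["a", "b", "c"], 2) == ["a", "c"]

    def test_ties_broken_by_input_order(self):
        assert sb.select_truncation([1.0, 1.0, 1.0], ["a", "b", "c"], 2) == ["a", "b"]

    def test_matches_full_sort_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 30))
            g = rng.normal(0, 1, n)
            k = int(rng.integers(1, n))
            ids = list(range(n))
            got = sb.select_truncation(g, ids, k)
            oracle = [i for _, i in sorted(zip(-g, ids))][:k]
            assert got == oracle

    def test_overselection_rejected(self):
        with pytest.raises(ValueError):
            sb.select_truncation([1.0, 2.0], ["a", "b"], 3)


class TestIndex:
    def test_single_trait_weight_preserves_ranking(self, rng):
        gy, ol = rng.normal(0, 2, 20), rng.normal(0, 3, 20)
        idx = sb.build_index(gy, ol, weights=(1.0, 0.0))
        assert np.array_equal(np.argsort(idx), np.argsort(gy))

    def test_identical_traits_double_zscore(self, rng):
        g = rng.normal(0, 1, 15)
        idx = sb.build_index(g, g)
        z = (g - g.mean()) / g.std()
        assert np.allclose(idx, 2 * z)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_zscores_standardized(self, seed):
        rng = np.random.default_rng(seed)
        g1, g2 = rng.normal(5, 3, 40), rng.normal(-2, 0.5, 40)
        idx = sb.build_index(g1, g2)
        z1 = (g1 - g1.mean()) / g1.std()
        assert abs((idx - z1).mean() - 0.0) < 1e-9  # second z-term has mean 0
        assert abs(idx.mean()) < 1e-9

    def test_degenerate_candidates_rejected(self):
        with pytest.raises(ValueError):
            sb.build_index(np.ones(5), np.arange(5.0))


class TestFitnessMatrix:
    def test_lambda_zero_is_midparent(self, rng):
        idx = rng.normal(0, 1, 6)
        fit = sb.build_fitness_matrix(idx, _grm(rng.normal(0, 1, (6, 6)), 6), 0.0)
        assert np.allclose(fit.values, (idx[:, None] + idx[None, :]) / 2)

    def test_arithmetic_example(self):
        idx = np.array([1.0, 2.0])
        G = np.array([[1.0, 0.5], [0.5, 1.0]])
        fit = sb.build_fitness_matrix(idx, _grm(G, 2), 0.5)
        assert fit.values[0, 1] == pytest.approx(1.25)  # 1.5 - 0.25

    def test_strictly_decreasing_in_coancestry(self, rng):
        idx = rng.normal(0, 1, 8)
        for _ in range(20):
            G1 = rng.normal(0, 1, (8, 8))
            G2 = G1.copy()
            G2[2, 5] += 0.7
            G2[5, 2] += 0.7
            f1 = sb.build_fitness_matrix(idx, _grm(G1, 8), 0.5)
            f2 = sb.build_fitness_matrix(idx, _grm(G2, 8), 0.5)
            assert f2.values[2, 5] < f1.values[2, 5]

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            sb.build_fitness_matrix(np.zeros(3), _grm(np.eye(4), 4), 0.5)


def _exhaustive_best(fit, n_crosses, cap):
    n = fit.values.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = -np.inf
    for combo in itertools.combinations(pairs, n_crosses):
        usage = {}
        for a, b in combo:
            usage[a] = usage.get(a, 0) + 1
            usage[b] = usage.get(b, 0) + 1
        if usage and max(usage.values()) > cap:
            continue
        best = max(best, sum(fit.values[a, b] for a, b in combo))
    return best


class TestGA:
    def test_attains_exhaustive_optimum_on_small_instances(self):
        """6 candidates, 3 crosses: the GA matches the enumerated optimum in
        at least 90% of 50 seeds."""
        wins = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            idx = r.normal(0, 1, 6)
            G = r.normal(0, 0.3, (6, 6))
            G = (G + G.T) / 2
            np.fill_diagonal(G, 1.0)
            fit = sb.build_fitness_matrix(idx, _grm(G, 6), 0.5)
            best = _exhaustive_best(fit, 3, cap=2)
            plan = sb.ga_optimize_crosses(
                fit, 3, 6, sb.GAConfig(pop_size=40, n_generations=60, seed=seed),
                usage_cap=2,
            )
            ids = {c: i for i, c in enumerate(fit.candidate_ids)}
            val = sum(fit.values[ids[a], ids[b]] for a, b in plan.crosses)
            wins += abs(val - best) < 1e-9
        assert wins >= 45

    def test_lambda_zero_selects_top_index_triangle(self):
        """With no penalty and cap 2, the optimal 3-cross plan is the
        triangle over the top-3 index candidates (total fitness = sum of the
        top-3 index values); the GA finds it."""
        idx = np.array([5.0, 4.0, 3.0, 0.5, 0.2, -1.0, -2.0, -3.0])
        fit = sb.build_fitness_matrix(idx, _grm(np.zeros((8, 8)), 8), 0.0)
        plan = sb.ga_optimize_crosses(
            fit, 3, 8, sb.GAConfig(pop_size=60, n_generations=80, seed=1), usage_cap=2
        )
        assert sorted(plan.parent_set) == [0, 1, 2]

    def test_twins_never_mated_under_large_penalty(self):
        """Two clones (GRM = 2 between them) with the best index values are
        never crossed together when the penalty dominates."""
        idx = np.array([3.0, 3.0, 1.0, 0.9, 0.8, 0.7])
        G = np.eye(6)
        G[0, 1] = G[1, 0] = 2.0
        fit = sb.build_fitness_matrix(idx, _grm(G, 6), 5.0)
        for seed in range(10):
            plan = sb.ga_optimize_crosses(
                fit, 3, 6, sb.GAConfig(pop_size=40, n_generations=60, seed=seed),
                usage_cap=2,
            )
            assert (0, 1) not in [tuple(sorted(c)) for c in plan.crosses]

    def test_beats_1000_random_valid_plans(self, rng):
        n = 40
        idx = rng.normal(0, 1, n)
        G = rng.normal(0, 0.2, (n, n))
        G = (G + G.T) / 2 + np.eye(n)
        fit = sb.build_fitness_matrix(idx, _grm(G, n), 0.5)
        plan = sb.ga_optimize_crosses(
            fit, 10, 15, sb.GAConfig(pop_size=60, n_generations=80, seed=3), usage_cap=2
        )
        ids = {c: i for i, c in enumerate(fit.candidate_ids)}
        val = sum(fit.values[ids[a], ids[b]] for a, b in plan.crosses)
        from safbreed.selection import _repair

        best_rand = -np.inf
        for _ in range(1000):
            raw = rng.integers(0, n, (10, 2))
            p = _repair(raw, n, 10, 15, 2, rng)
            best_rand = max(best_rand, plan_objective(p, fit.values))
        assert val >= best_rand

    def test_plan_respects_constraints(self, rng):
        n = 100
        idx = rng.normal(0, 1, n)
        fit = sb.build_fitness_matrix(idx, _grm(np.eye(n), n), 0.5)
        plan = sb.ga_optimize_crosses(
            fit, 30, 50, sb.GAConfig(pop_size=40, n_generations=30, seed=5), usage_cap=2
        )
        assert len(plan.crosses) == 30
        assert len(plan.parent_set) <= 50
        assert all(a != b for a, b in plan.crosses)
        assert len({tuple(sorted(c)) for c in plan.crosses}) == 30

    def test_infeasible_instances_rejected(self):
        fit = sb.build_fitness_matrix(np.zeros(3), _grm(np.eye(3), 3), 0.0)
        with pytest.raises(ValueError):
            sb.ga_optimize_crosses(fit, 5, 3, sb.GAConfig(pop_size=10, n_generations=5),
                                   usage_cap=2)


class TestSelectParents:
    def _gebv_table(self, rng, n):
        return pd.DataFrame(
            {"GY": rng.normal(0, 1, n), "OL": rng.normal(0, 1, n)},
            index=[f"c{i}" for i in range(n)],
        )

    def test_single_trait_dispatch(self, rng):
        tbl = self._gebv_table(rng, 30)
        cfg = sb.StrategyConfig(strategy="GY", n_parents=10, n_crosses=5)
        sel, plan = sb.select_parents(cfg, tbl, None, list(tbl.index), rng)
        assert sel == sb.select_truncation(tbl["GY"].to_numpy(), list(tbl.index), 10)
        assert len(plan.crosses) == 5
        assert set(p for c in plan.crosses for p in c) <= set(sel)

    def test_index_dispatch_selection_differential(self, rng):
        tbl = self._gebv_table(rng, 60)
        cfg = sb.StrategyConfig(strategy="GY_plus_OL", n_parents=20, n_crosses=8)
        sel, _ = sb.select_parents(cfg, tbl, None, list(tbl.index), rng)
        idx = sb.build_index(tbl["GY"].to_numpy(), tbl["OL"].to_numpy())
        sel_mask = tbl.index.isin(sel)
        assert idx[sel_mask].mean() >= idx.mean()

    def test_rel_lambda_zero_matches_index_truncation_parents(self, rng):
        """In the no-penalty limit the GA's parent set (spread over exactly
        n_parents candidates) is the same set truncation on the index picks."""
        tbl = self._gebv_table(rng, 12)
        grm = _grm(np.eye(12), 12)
        grm.individual_ids = list(tbl.index)
        cfg = sb.StrategyConfig(
            strategy="GY_plus_OL_Rel", n_parents=6, n_crosses=3, lam=0.0,
            ga=sb.GAConfig(pop_size=60, n_generations=80, seed=2),
        )
        sel, plan = sb.select_parents(cfg, tbl, grm, list(tbl.index), rng)
        idx = sb.build_index(tbl["GY"].to_numpy(), tbl["OL"].to_numpy())
        top6 = set(sb.select_truncation(idx, list(tbl.index), 6))
        assert set(sel) == top6
        assert len(plan.crosses) == 3

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            sb.StrategyConfig(strategy="PS")

    def test_random_plan_pairs_distinct(self, rng):
        plan = sb.random_cross_plan(list("abcdefgh"), 10, rng)
        keys = [tuple(sorted(c)) for c in plan.crosses]
        assert len(set(keys)) == 10
        assert all(a != b for a, b in plan.crosses)
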