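"""SRVS core: shuffling, partitioning, block solves, stopping rules, ensemble runs."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from srvs.core import (SRVSConfig, SRVSState, check_convergence,
                       coverage_min_iterations, fisher_yates_permutation,
                       partition, run_srvs, solve_block)
from srvs.io import matrix_from_frame, normalize_columns

import pandas as pd


def _normalized(X):
    X = X - X.mean(axis=0)
    n = np.linalg.norm(X, axis=0)
    n[n == 0] = 1.0
    return X / n


class TestFisherYates:
    def test_single_element(self, rng):
        assert fisher_yates_permutation(1, rng).tolist() == [0]

    def test_deterministic_under_fixed_seed(self):
        a = fisher_yates_permutation(50, np.random.default_rng(9))
        b = fisher_yates_permutation(50, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_uniform_over_permutations_of_four(self):
        """Chi-square goodness of fit over all 24 permutations, 24000 draws."""
        rng = np.random.default_rng(2024)
        counts = {}
        for _ in range(24000):
            key = tuple(fisher_yates_permutation(4, rng))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 24
        chi2 = sum((c - 1000) ** 2 / 1000 for c in counts.values())
        assert chi2 < stats.chi2.ppf(0.999, df=23)


class TestPartition:
    def test_even_split(self):
        blocks = partition(np.arange(10), 5)
        assert [len(b) for b in blocks] == [5, 5]

    def test_width_one_remainder_merged(self):
        blocks = partition(np.arange(11), 5)
        assert [len(b) for b in blocks] == [5, 6]

    def test_remainder_of_two_kept(self):
        blocks = partition(np.arange(12), 5)
        assert [len(b) for b in blocks] == [5, 5, 2]

    @given(n=st.integers(2, 200), k=st.integers(2, 50))
    @settings(max_examples=60, deadline=None)
    def test_blocks_partition_all_indices(self, n, k):
        if k > n:
            with pytest.raises(ValueError):
                partition(np.arange(n), k)
            return
        blocks = partition(np.arange(n), k)
        flat = np.concatenate(blocks)
        assert sorted(flat.tolist()) == list(range(n))
        assert all(len(b) >= 2 for b in blocks) or n < 2


class TestSolveBlock:
    @pytest.mark.parametrize("p", [0, 1])
    def test_orthonormal_single_column_target(self, p, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((8, 8)))
        y = 3.0 * Q[:, 2]
        coef = solve_block(y, Q, SRVSConfig(p=p, epsilon_rel=0.01))
        expected = np.zeros(8)
        expected[2] = 3.0
        assert np.allclose(coef, expected, atol=1e-8)

    @pytest.mark.parametrize("p", [0, 1])
    def test_constraint_satisfied_at_zero_returns_zero(self, p):
        # y orthogonal to every column and eps >= ||y||
        X = np.eye(4)[:, :3]
        y = np.array([0.0, 0.0, 0.0, 2.0])
        coef = solve_block(y, X, SRVSConfig(p=p), eps=np.linalg.norm(y))
        assert np.all(coef == 0)

    @pytest.mark.parametrize("p", [0, 1])
    def test_zero_phenotype_returns_zero(self, p):
        coef = solve_block(np.zeros(5), np.eye(5), SRVSConfig(p=p))
        assert np.all(coef == 0)

    @pytest.mark.parametrize("p", [0, 1])
    def test_zero_columns_never_selected(self, p, rng):
        X = _normalized(rng.standard_normal((20, 6)))
        X[:, 3] = 0.0
        y = rng.standard_normal(20)
        coef = solve_block(y, X, SRVSConfig(p=p, epsilon_rel=0.5))
        assert coef[3] == 0.0

    def test_max_sparsity_respected(self, rng):
        X = _normalized(rng.standard_normal((15, 30)))
        y = rng.standard_normal(15)
        for p in (0, 1):
            coef = solve_block(y, X, SRVSConfig(p=p, max_sparsity=4, epsilon_rel=0.01))
            assert np.count_nonzero(coef) <= 4

    def test_omp_matches_brute_force_on_small_instances(self, rng):
        """Greedy solve equals exhaustive best-subset search on well-separated targets."""
        from itertools import combinations
        for _ in range(20):
            Q, _ = np.linalg.qr(rng.standard_normal((10, 10)))
            X = Q[:, :8].T.copy()
            X /= np.linalg.norm(X, axis=0)
            support = rng.choice(10, 2, replace=False)
            y = 4.0 * X[:, support[0]] - 1.0 * X[:, support[1]]
            coef = solve_block(y, X, SRVSConfig(p=0, max_sparsity=2, epsilon_rel=0.01))
            best = min(
                (np.linalg.norm(y - X[:, list(S)] @ np.linalg.lstsq(X[:, list(S)], y, rcond=None)[0]), S)
                for S in combinations(range(10), 2))
            assert set(np.flatnonzero(coef)) == set(best[1])


class TestCoverageRule:
    def test_single_block_needs_one_iteration(self):
        assert coverage_min_iterations(10, 10, 0.01) == 1

    def test_closed_form_example(self):
        # q = 4/9, L = ceil(ln 0.01 / ln(5/9)) = 8
        assert coverage_min_iterations(10, 5, 0.01) == 8

    def test_pair_cooccurrence_probability_matches_q(self):
        """Monte Carlo estimate of the per-iteration pair probability."""
        rng = np.random.default_rng(77)
        n, k, trials = 10, 5, 20000
        hits = 0
        for _ in range(trials):
            perm = rng.permutation(n)
            blocks = partition(perm, k)
            for b in blocks:
                if 0 in b and 1 in b:
                    hits += 1
        q = (k - 1) / (n - 1)
        se = np.sqrt(q * (1 - q) / trials)
        assert abs(hits / trials - q) < 4 * se

    def test_monotone_non_increasing_in_k(self):
        values = [coverage_min_iterations(100, k, 0.05) for k in range(2, 101)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_union_bound_is_more_demanding(self):
        assert (coverage_min_iterations(50, 10, 0.05, union_bound=True)
                > coverage_min_iterations(50, 10, 0.05))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            coverage_min_iterations(5, 6, 0.05)
        with pytest.raises(ValueError):
            coverage_min_iterations(10, 5, 1.5)


class TestCheckConvergence:
    def _state(self, accum, iteration, prev_avg):
        return SRVSState(delta_accum=accum, iteration=iteration, prev_avg=prev_avg,
                         selection_count=np.zeros(len(accum), dtype=int), y_norm=1.0)

    def test_identical_averages_converge(self):
        avg = np.array([1.0, 2.0])
        state = self._state(avg * 3, 3, avg.copy())
        assert check_convergence(state, 1e-12)

    def test_unit_vector_gap_fails_half_threshold(self):
        state = self._state(np.array([1.0, 0.0]) * 2, 2, np.array([0.0, 0.0]))
        assert not check_convergence(state, 0.5)

    def test_infinite_threshold_converges_from_iteration_two(self):
        state = self._state(np.array([5.0, -3.0]), 2, np.array([9.0, 9.0]))
        assert check_convergence(state, np.inf)

    def test_insufficient_history(self):
        state = self._state(np.array([1.0]), 1, None)
        assert not check_convergence(state, np.inf)


def _instance(m, n, seed, signal=True):
    rng = np.random.default_rng(seed)
    X = _normalized(rng.standard_normal((m, n)))
    if signal:
        beta = np.zeros(n)
        beta[rng.choice(n, 3, replace=False)] = rng.normal(0, 5, 3)
        y = X @ beta + 0.1 * rng.standard_normal(m)
    else:
        y = rng.standard_normal(m)
    return X, y


class TestRunSrvs:
    def test_bit_identical_under_fixed_seed(self):
        X, y = _instance(20, 60, 1)
        cfg = SRVSConfig(k=15, alpha=0.05, p_stop=0.2, seed=42)
        a, b = run_srvs(y, X, cfg), run_srvs(y, X, cfg)
        assert np.array_equal(a.delta_avg, b.delta_avg)
        assert np.array_equal(a.selection_count, b.selection_count)
        assert a.n_iterations == b.n_iterations

    def test_support_contained_in_selected_variables(self):
        X, y = _instance(20, 60, 2)
        res = run_srvs(y, X, SRVSConfig(k=15, alpha=0.05, p_stop=0.2, seed=0))
        assert np.all(res.selection_count[res.delta_avg != 0] > 0)
        assert np.all(res.delta_avg[res.selection_count == 0] == 0)

    @pytest.mark.parametrize("p", [0, 1])
    def test_scale_equivariance(self, p):
        X, y = _instance(25, 50, 3)
        cfg = SRVSConfig(k=20, p=p, alpha=0.05, p_stop=0.2, seed=5)
        a = run_srvs(y, X, cfg)
        b = run_srvs(3.5 * y, X, cfg)
        assert a.n_iterations == b.n_iterations
        assert np.allclose(b.delta_avg, 3.5 * a.delta_avg, rtol=1e-9, atol=1e-12)

    def test_single_block_collapses_to_direct_solve(self):
        """With k = n the ensemble average equals one full-matrix solve."""
        for seed in range(3):
            X, y = _instance(20, 35, seed)
            cfg = SRVSConfig(k=35, p=1, alpha=1e-12, p_stop=0.5, max_iter=1, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = run_srvs(y, X, cfg)
            direct = solve_block(y, X, cfg)
            assert np.allclose(res.delta_avg, direct, atol=1e-10)

    def test_zero_phenotype_terminates_at_coverage_bound(self):
        X, _ = _instance(10, 30, 4)
        cfg = SRVSConfig(k=10, p_stop=0.1, seed=0)
        res = run_srvs(np.zeros(10), X, cfg)
        assert np.all(res.delta_avg == 0)
        assert res.n_iterations == res.min_iterations
        assert res.converged_rule_a and res.coverage_satisfied

    def test_max_iter_reached_warns(self):
        X, y = _instance(15, 40, 5)
        with pytest.warns(UserWarning, match="max_iter"):
            res = run_srvs(y, X, SRVSConfig(k=10, alpha=1e-15, max_iter=3, seed=1))
        assert res.n_iterations == 3
        assert not (res.converged_rule_a and res.coverage_satisfied)

    def test_requires_normalized_matrix(self, small_dataset):
        geno, expr, pheno = small_dataset.as_pipeline_inputs()
        from srvs.io import merge_and_filter
        merged, _ = merge_and_filter(geno, expr, pheno)
        with pytest.raises(ValueError, match="normalized"):
            run_srvs(np.zeros(merged.n_subjects), merged)

    def test_dimension_mismatch_rejected(self):
        X, y = _instance(10, 20, 6)
        with pytest.raises(ValueError, match="rows"):
            run_srvs(y[:-1], X, SRVSConfig(k=10))

    def test_omics_matrix_input(self, small_dataset, rng):
        frame = pd.DataFrame(rng.normal(size=(30, 12)),
                             index=[f"s{i}" for i in range(30)])
        m = normalize_columns(matrix_from_frame(frame, "expression"))
        y = rng.standard_normal(30)
        res = run_srvs(y, m, SRVSConfig(k=6, alpha=0.1, p_stop=0.3, seed=2))
        assert res.delta_avg.shape == (12,)


def test_config_validation():
    with pytest.raises(ValueError):
        SRVSConfig(p=2).validate()
    with pytest.raises(ValueError):
        SRVSConfig(epsilon_rel=1.5).validate()
    with pytest.raises(ValueError):
        SRVSConfig(k=1).validate()
    with pytest.raises(ValueError):
        SRVSConfig(k=100).validate(m=10, n=50)
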