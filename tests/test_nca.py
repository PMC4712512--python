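"""NCA criteria, reduction, alternating least squares, and normalization."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from mirnca import (
    ConnectivityPattern,
    TimeGrid,
    check_nca_criteria,
    generate_expression,
    generate_ground_truth,
    nca_decompose,
    normalize_decomposition,
    reduce_to_compatible,
)
from mirnca.nca import IncompatiblePatternError, NoCompatibleSubnetworkError


def pattern(support, regs=None, tgs=None):
    support = np.asarray(support, dtype=np.int8)
    n, l = support.shape
    regs = regs or [f"r{j}" for j in range(l)]
    tgs = tgs or [f"t{i}" for i in range(n)]
    return ConnectivityPattern(regs, tgs, support)


def brute_force_criteria(Z0, n_timepoints, n_draws=100, seed=123):
    """Independent oracle: criteria via numeric ranks of many random draws."""
    rng = np.random.default_rng(seed)
    L = Z0.n_regulators

    def max_rank(sup):
        if sup.size == 0 or sup.sum() == 0:
            return 0
        return max(
            np.linalg.matrix_rank(sup * rng.standard_normal(sup.shape))
            for _ in range(n_draws)
        )

    c1 = max_rank(Z0.support) == L
    c2 = {}
    for j, reg in enumerate(Z0.regulators):
        sub = Z0.support[Z0.support[:, j] == 0][:, np.arange(L) != j]
        c2[reg] = max_rank(sub) == L - 1
    return c1, c2, n_timepoints >= L


class TestCriteria:
    def test_block_diagonal_disjoint_triples_pass(self):
        sup = np.kron(np.eye(3, dtype=np.int8), np.ones((3, 1), dtype=np.int8))
        report = check_nca_criteria(pattern(sup), n_timepoints=8)
        assert report.all_pass

    def test_duplicate_target_sets_fail_criterion2(self):
        sup = np.array([[1, 1, 0], [1, 1, 0], [1, 1, 1], [0, 0, 1], [0, 0, 1]])
        report = check_nca_criteria(pattern(sup), n_timepoints=8)
        assert not report.criterion2["r0"]
        assert not report.criterion2["r1"]
        assert set(report.offending_regulators) >= {"r0", "r1"}

    def test_too_few_timepoints_fail_criterion3(self):
        sup = np.eye(5, dtype=np.int8)
        sup = np.vstack([sup, np.ones((2, 5), dtype=np.int8)])
        report = check_nca_criteria(pattern(sup), n_timepoints=3)
        assert not report.criterion3
        assert not report.all_pass

    def test_oracle_equivalence_on_small_patterns(self):
        """Checker agrees with a 100-draw numeric-rank oracle, L<=6, N<=15."""
        rng = np.random.default_rng(0)
        cases = []
        for _ in range(30):
            L = int(rng.integers(2, 7))
            N = int(rng.integers(L + 1, 16))
            sup = (rng.random((N, L)) < 0.4).astype(np.int8)
            sup[rng.integers(0, N, size=L), np.arange(L)] = 1  # no empty column
            sup[sup.sum(axis=1) == 0, 0] = 1  # no empty row
            cases.append(pattern(sup))
        # pathological: duplicated columns, nested supports
        dup = np.array([[1, 1], [1, 1], [1, 1]], dtype=np.int8)
        nested = np.array([[1, 1], [1, 1], [1, 0]], dtype=np.int8)
        cases += [pattern(dup), pattern(nested)]
        for Z0 in cases:
            for M in (Z0.n_regulators - 1, Z0.n_regulators + 2):
                report = check_nca_criteria(Z0, M)
                c1, c2, c3 = brute_force_criteria(Z0, M)
                assert report.criterion1 == c1
                assert report.criterion2 == c2
                assert report.criterion3 == c3


class TestReduce:
    def test_compatible_pattern_is_fixed_point(self):
        truth = generate_ground_truth(4, 20, seed=3)
        reduced, log = reduce_to_compatible(truth.Z0, n_timepoints=17)
        assert log == []
        assert np.array_equal(reduced.support, truth.Z0.support)

    def test_duplicated_regulator_removed(self):
        truth = generate_ground_truth(4, 20, seed=4)
        Z0 = truth.Z0
        # append a duplicate of the smallest regulator under a new ID
        degs = Z0.support.sum(axis=0)
        j = int(np.argmin(degs))
        support = np.hstack([Z0.support, Z0.support[:, [j]]])
        bad = ConnectivityPattern(Z0.regulators + ["zz-dup"], Z0.targets, support)
        assert not check_nca_criteria(bad, 17).all_pass
        reduced, log = reduce_to_compatible(bad, n_timepoints=17)
        assert len(log) == 1
        assert check_nca_criteria(reduced, 17).all_pass
        assert reduced.n_regulators == Z0.n_regulators

    def test_all_identical_regulators_collapse_to_one(self):
        """Fully duplicated regulators are indistinguishable pairwise, but a
        single surviving regulator over the shared targets is identifiable
        (rank-1), so greedy removal terminates there."""
        sup = np.ones((4, 3), dtype=np.int8)
        reduced, log = reduce_to_compatible(pattern(sup), n_timepoints=8)
        assert reduced.n_regulators == 1
        assert len(log) == 2
        assert check_nca_criteria(reduced, 8).all_pass


class TestDecompose:
    def test_noiseless_exact_recovery(self, small_truth, small_expression):
        dec = nca_decompose(small_expression, small_truth.Z0, seed=1)
        E = small_expression
        assert dec.residual_trace[-1] < 1e-8 * np.linalg.norm(E)
        corr = np.abs(np.corrcoef(dec.T, small_truth.T_true)[:3, 3:])
        rows, cols = linear_sum_assignment(-corr)
        assert np.all(corr[rows, cols] > 0.999)

    def test_zero_activity_regulator_flagged(self, small_truth):
        small_truth.T_true[1] = 0.0
        E = generate_expression(small_truth)
        dec = nca_decompose(E, small_truth.Z0, seed=2)
        assert small_truth.Z0.regulators[1] in dec.zero_activity
        assert np.all(dec.T[1] == 0.0)

    def test_noisy_recovery_default_scale(self):
        """Mean |activity correlation| >= 0.95 at 5% noise (10 seeds)."""
        scores = []
        for seed in range(10):
            truth = generate_ground_truth(10, 120, noise_sd=0.0, seed=seed)
            signal_sd = (truth.C_true @ truth.T_true).std()
            truth.noise_sd = 0.05 * signal_sd
            E = generate_expression(truth)
            dec = nca_decompose(E, truth.Z0, seed=seed + 100)
            corr = np.abs(np.corrcoef(dec.T, truth.T_true)[:10, 10:])
            rows, cols = linear_sum_assignment(-corr)
            scores.append(corr[rows, cols].mean())
        assert np.mean(scores) >= 0.95

    def test_recovery_degrades_gracefully_with_noise(self):
        means = []
        for frac in (0.0, 0.05, 0.1, 0.2):
            scores = []
            for seed in (0, 1, 2):
                truth = generate_ground_truth(6, 60, noise_sd=0.0, seed=seed)
                truth.noise_sd = frac * (truth.C_true @ truth.T_true).std()
                E = generate_expression(truth)
                dec = nca_decompose(E, truth.Z0, seed=seed + 10)
                corr = np.abs(np.corrcoef(dec.T, truth.T_true)[:6, 6:])
                rows, cols = linear_sum_assignment(-corr)
                scores.append(corr[rows, cols].mean())
            means.append(np.mean(scores))
        assert all(a >= b - 1e-6 for a, b in zip(means, means[1:]))

    def test_residual_trace_monotone(self, small_truth):
        small_truth.noise_sd = 0.2
        E = generate_expression(small_truth)
        for seed in range(5):
            dec = nca_decompose(E, small_truth.Z0, n_restarts=1, seed=seed)
            trace = np.asarray(dec.residual_trace)
            assert np.all(np.diff(trace) <= 1e-9 * trace[0])

    def test_incompatible_pattern_refused(self, small_expression, small_truth):
        Z0 = small_truth.Z0
        bad_support = Z0.support.copy()
        bad_support[:, 1] = bad_support[:, 0]
        bad = ConnectivityPattern(Z0.regulators, Z0.targets, bad_support)
        with pytest.raises(IncompatiblePatternError, match="reduce_to_compatible"):
            nca_decompose(small_expression, bad, seed=0)

    def test_rank1_matches_truncated_svd(self):
        """With one regulator the solution is the rank-1 SVD up to gauge."""
        grid = TimeGrid(tuple(float(t) for t in np.linspace(0, 4320, 9)))
        rng = np.random.default_rng(9)
        c = rng.uniform(0.5, 2, size=6)
        t = np.sin(2 * np.pi * grid.array / grid.span)
        E = np.outer(c, t)
        Z0 = pattern(np.ones((6, 1), dtype=np.int8))
        dec = nca_decompose(E, Z0, seed=0)
        u, s, vt = np.linalg.svd(E)
        rank1 = s[0] * np.outer(u[:, 0], vt[0])
        assert np.allclose(dec.C @ dec.T, rank1, atol=1e-8)
        r = np.corrcoef(dec.T[0], vt[0])[0, 1]
        assert abs(r) > 1 - 1e-10


class TestNormalize:
    def test_idempotent(self):
        rng = np.random.default_rng(10)
        C = rng.normal(size=(8, 3))
        T = rng.normal(size=(3, 6))
        C1, T1, _ = normalize_decomposition(C, T)
        C2, T2, _ = normalize_decomposition(C1, T1)
        assert np.allclose(C1, C2) and np.allclose(T1, T2)

    def test_gauge_invariance(self):
        rng = np.random.default_rng(11)
        C = rng.normal(size=(8, 3))
        T = rng.normal(size=(3, 6))
        S = np.diag([-3.0, 0.5, 7.0])
        C1, T1, _ = normalize_decomposition(C, T)
        C2, T2, _ = normalize_decomposition(C @ S, np.linalg.inv(S) @ T)
        assert np.allclose(C1, C2) and np.allclose(T1, T2)

    def test_product_preserved(self):
        rng = np.random.default_rng(12)
        C = rng.normal(size=(10, 4))
        T = rng.normal(size=(4, 7))
        C1, T1, _ = normalize_decomposition(C, T)
        prod = C @ T
        assert np.linalg.norm(C1 @ T1 - prod) <= 1e-12 * np.linalg.norm(prod)
        assert np.allclose(np.max(np.abs(T1), axis=1), 1.0)
        assert np.all(C1.sum(axis=0) >= 0)

    def test_zero_row_flagged(self):
        C = np.ones((4, 2))
        T = np.vstack([np.ones(5), np.zeros(5)])
        _, T1, flagged = normalize_decomposition(C, T)
        assert flagged == [1]
        assert np.all(T1[1] == 0)
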