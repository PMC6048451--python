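import itertools

import numpy as np
import pytest

from rewirekit import datagen
from rewirekit.exprio import ExpressionMatrix
from rewirekit.matequiv import (
    CorrMatrix,
    jennrich_test,
    permutation_equivalence_test,
    spearman_corr,
    steiger_test,
)


def _em(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values,
    )


def _cm(r, n, genes=("a", "b")):
    G = len(genes)
    M = np.full((G, G), float(r))
    np.fill_diagonal(M, 1.0)
    return CorrMatrix(list(genes), M, n)


class TestSpearman:
    def test_monotone_pair_r_one(self):
        m = _em([[1, 2, 3, 4, 5], [10, 20, 30, 40, 50]])
        R, P = spearman_corr(m)
        assert R.values[0, 1] == pytest.approx(1.0)

    def test_hand_rank_computation(self):
        # x = 1..5 vs y = (1,2,3,5,4): r = 1 - 6*2/(5*24) = 0.9
        m = _em([[1, 2, 3, 4, 5], [1, 2, 3, 5, 4]])
        R, _ = spearman_corr(m)
        assert R.values[0, 1] == pytest.approx(0.9)

    def test_diagonal(self):
        m = _em(np.random.default_rng(0).normal(size=(3, 6)))
        R, P = spearman_corr(m)
        np.testing.assert_allclose(np.diag(R.values), 1.0)
        np.testing.assert_array_equal(np.diag(P), 0.0)

    def test_matches_scipy(self, rng):
        values = rng.normal(size=(5, 20))
        from scipy.stats import spearmanr

        R, P = spearman_corr(_em(values))
        ref_r, ref_p = spearmanr(values, axis=1)
        np.testing.assert_allclose(R.values, ref_r, atol=1e-12)
        offdiag = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(P[offdiag], ref_p[offdiag], atol=1e-9)

    def test_constant_gene_flagged_zero(self):
        m = _em([[1, 1, 1, 1, 1], [1, 2, 3, 4, 5]])
        with pytest.warns(UserWarning, match="constant"):
            R, _ = spearman_corr(m)
        assert R.values[0, 1] == 0.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="4 samples"):
            spearman_corr(_em([[1, 2, 3], [3, 2, 1]]))


class TestSteiger:
    def test_equal_matrices_zero(self):
        R = _cm(0.4, 50)
        assert steiger_test(R, R).statistic == 0.0

    def test_closed_form_toy(self):
        # atanh(0.5)^2 / (1/100 + 1/100) = 15.0869, df = 1
        res = steiger_test(_cm(0.5, 103), _cm(0.0, 103))
        assert res.statistic == pytest.approx(np.arctanh(0.5) ** 2 / 0.02, rel=1e-12)
        assert res.statistic == pytest.approx(15.09, abs=0.01)
        assert res.df == 1

    def test_symmetry(self, rng):
        A = datagen.random_psd_corr(4, rng)
        B = datagen.random_psd_corr(4, rng)
        genes = list("abcd")
        r1 = CorrMatrix(genes, A, 30)
        r2 = CorrMatrix(genes, B, 60)
        assert steiger_test(r1, r2).statistic == pytest.approx(
            steiger_test(r2, r1).statistic, rel=1e-12
        )

    def test_gene_reordering_invariance(self, rng):
        A = datagen.random_psd_corr(4, rng)
        B = datagen.random_psd_corr(4, rng)
        genes = list("abcd")
        perm = [2, 0, 3, 1]
        stat1 = steiger_test(CorrMatrix(genes, A, 30), CorrMatrix(genes, B, 30)).statistic
        gp = [genes[i] for i in perm]
        Ap, Bp = A[np.ix_(perm, perm)], B[np.ix_(perm, perm)]
        stat2 = steiger_test(CorrMatrix(gp, Ap, 30), CorrMatrix(gp, Bp, 30)).statistic
        assert stat1 == pytest.approx(stat2, rel=1e-12)

    def test_perfect_correlation_rejected(self):
        M = np.array([[1.0, 1.0], [1.0, 1.0]])
        R = CorrMatrix(["a", "b"], M, 20)
        with pytest.raises(ValueError, match="diverges"):
            steiger_test(R, _cm(0.0, 20))

    def test_null_mean_near_df(self, rng):
        # chi-square calibration: null mean ~ df = G(G-1)/2 (G = 5 -> 10)
        stats = []
        for _ in range(400):
            X = rng.standard_normal((5, 100))
            Y = rng.standard_normal((5, 100))
            R1 = CorrMatrix(list("abcde"), np.corrcoef(X), 100, "pearson")
            R2 = CorrMatrix(list("abcde"), np.corrcoef(Y), 100, "pearson")
            stats.append(steiger_test(R1, R2).statistic)
        assert np.mean(stats) == pytest.approx(10.0, rel=0.10)


class TestJennrich:
    def test_equal_matrices_zero(self):
        R = _cm(0.4, 50)
        assert jennrich_test(R, R).statistic == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_toy(self):
        # Rbar = I, Z = 5 (R1 - R2): chi2 = 9 exactly, df = 1
        res = jennrich_test(_cm(0.3, 50), _cm(-0.3, 50))
        assert res.statistic == pytest.approx(9.0, abs=1e-10)
        assert res.df == 1

    def test_null_mean_near_df(self, rng):
        stats = []
        for _ in range(400):
            X = rng.standard_normal((4, 200))
            Y = rng.standard_normal((4, 200))
            R1 = CorrMatrix(list("abcd"), np.corrcoef(X), 200, "pearson")
            R2 = CorrMatrix(list("abcd"), np.corrcoef(Y), 200, "pearson")
            stats.append(jennrich_test(R1, R2).statistic)
        assert np.mean(stats) == pytest.approx(6.0, rel=0.15)

    def test_singular_pooled_matrix_advises(self):
        M = np.array([[1.0, 1.0], [1.0, 1.0]])
        R1 = CorrMatrix(["a", "b"], M, 10)
        R2 = CorrMatrix(["a", "b"], M, 10)
        with pytest.raises(ValueError, match="[Ss]hrinkage|[Ss]teiger"):
            jennrich_test(R1, R2)

    def test_shrinkage_runs_on_singular(self):
        M = np.array([[1.0, 1.0], [1.0, 1.0]])
        R1 = CorrMatrix(["a", "b"], M, 10)
        R2 = _cm(0.0, 10)
        res = jennrich_test(R1, R2, shrinkage=0.1)
        assert np.isfinite(res.statistic)


class TestPermutationTest:
    def test_planted_rewiring_power(self, rewired_cohort):
        matrix, labels = rewired_cohort
        res = permutation_equivalence_test(matrix, labels, n_permutations=199, seed=1)
        assert res.p_simulated <= 0.01

    def test_floor_at_n_plus_one(self, rewired_cohort):
        matrix, labels = rewired_cohort
        res = permutation_equivalence_test(matrix, labels, n_permutations=199, seed=1)
        assert res.p_simulated >= 1.0 / 200
        # the 10,000-permutation grid can represent 5e-4 (Table-4-style p)
        # 5/10001 = 4.9995e-4 prints as 5.00E-04 at table precision
        grid = (np.arange(1, 10002)) / 10001.0
        assert np.isclose(grid, 5.0e-4, rtol=1e-3).any()

    def test_small_class_rejected(self, rewired_cohort):
        matrix, _ = rewired_cohort
        labels = np.zeros(matrix.n_samples, dtype=int)
        labels[:3] = 1
        with pytest.raises(ValueError, match="< 4"):
            permutation_equivalence_test(matrix, labels, n_permutations=99)

    # y has no monotone subsequence of length 4 (longest inc/dec run = 3),
    # so no 4-sample assignment yields |spearman r| = 1 in either group
    _X8 = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
    _Y8 = np.array([3.0, 2, 1, 6, 5, 4, 8, 7])

    def test_exhaustive_matches_enumeration_oracle(self):
        # n = 8 samples, two classes of 4, G = 2: enumerate all C(8,4)
        # assignments by brute force and compare exactly
        values = np.vstack([self._X8, self._Y8])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        m = _em(values)
        res = permutation_equivalence_test(m, labels, method="steiger",
                                           exhaustive=True)

        def steiger_stat(idx_a):
            idx_a = np.array(idx_a)
            idx_b = np.setdiff1d(np.arange(8), idx_a)
            from scipy.stats import rankdata

            def corr(idx):
                r = np.corrcoef(rankdata(values[:, idx], axis=1))[0, 1]
                return r

            z1, z2 = np.arctanh(corr(idx_a)), np.arctanh(corr(idx_b))
            return (z1 - z2) ** 2 / (1.0 / 1 + 1.0 / 1)

        obs = steiger_stat([0, 1, 2, 3])
        others = [
            steiger_stat(c)
            for c in itertools.combinations(range(8), 4)
            if set(c) != {0, 1, 2, 3}
        ]
        expected = (1 + sum(s > obs for s in others)) / (len(others) + 1)
        assert res.p_simulated == pytest.approx(expected, abs=1e-12)
        assert res.n_null == len(others)

    def test_sampled_p_converges_to_exhaustive(self):
        values = np.vstack([self._X8, self._Y8])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        m = _em(values)
        exact = permutation_equivalence_test(m, labels, exhaustive=True).p_simulated
        sampled = permutation_equivalence_test(
            m, labels, n_permutations=4000, seed=3
        ).p_simulated
        assert sampled == pytest.approx(exact, abs=0.05)

    def test_label_polarity_symmetry(self, rewired_cohort):
        matrix, labels = rewired_cohort
        a = permutation_equivalence_test(matrix, labels, n_permutations=99, seed=4)
        b = permutation_equivalence_test(matrix, 1 - labels, n_permutations=99, seed=4)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)
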