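"""Quality control, GRM construction and synthetic panel generation."""
import numpy as np
import pytest
from scipy import stats

from mtvc.genotypes import (
    MISSING,
    GenotypeMatrix,
    QCThresholds,
    allele_frequencies,
    cholesky_psd,
    compute_grm,
    hwe_pvalues,
    qc_filter,
    synthetic_genotypes,
)


def _hw_column(n_animals: int) -> np.ndarray:
    """Exact Hardy-Weinberg counts at p = 0.5: (n/4, n/2, n/4)."""
    q = n_animals // 4
    return np.array([0] * q + [1] * (n_animals - 2 * q) + [2] * q)


def _toy_panel():
    """20 animals x 10 SNPs; SNPs 0-6 pass QC, 7 fails MAF, 8 fails call
    rate, 9 fails Hardy-Weinberg."""
    n = 20
    good = _hw_column(n)
    cols = [np.roll(good, k) for k in range(7)]
    maf_fail = np.zeros(n, dtype=int)
    maf_fail[0] = 1  # p = 1/40 = 0.025 < 0.05
    call_fail = good.copy()
    call_fail[:2] = MISSING  # call rate 0.9 < 0.95
    hwe_fail = np.ones(n, dtype=int)  # all heterozygous: chi2 = n
    cols += [maf_fail, call_fail, hwe_fail]
    return GenotypeMatrix(codes=np.column_stack(cols))


def _qc_oracle(codes, thr):
    """Direct per-SNP counting oracle re-deriving every QC statistic."""
    kept = []
    for j in range(codes.shape[1]):
        col = codes[:, j]
        obs = col[col != MISSING]
        call_rate = len(obs) / len(col)
        if len(obs) == 0:
            continue
        n0 = np.sum(obs == 0)
        n1 = np.sum(obs == 1)
        n2 = np.sum(obs == 2)
        p = (2 * n2 + n1) / (2 * len(obs))
        maf = min(p, 1 - p)
        if 0 < p < 1:
            e = len(obs) * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
            chi2 = np.sum((np.array([n0, n1, n2]) - e) ** 2 / e)
            hwe_p = stats.chi2.sf(chi2, 1)
        else:
            hwe_p = 1.0
        if maf >= thr.maf_min and call_rate >= thr.call_rate_min and hwe_p >= thr.hwe_p_min:
            kept.append(j)
    return kept


class TestQCFilter:
    def test_monomorphic_snp_removed_by_maf(self):
        g = GenotypeMatrix(codes=np.array([[0, 1], [0, 1], [0, 0], [0, 2]]))
        filtered, kept = qc_filter(g)
        assert list(kept) == [1]

    def test_toy_panel_matches_counting_oracle(self):
        g = _toy_panel()
        thr = QCThresholds()
        filtered, kept = qc_filter(g, thr)
        assert list(kept) == _qc_oracle(g.codes, thr) == list(range(7))
        assert filtered.n_snps == 7
        # order of retained SNPs preserved
        assert filtered.snp_ids == [g.snp_ids[j] for j in kept]

    def test_default_thresholds_match_stated_filter_semantics(self):
        thr = QCThresholds()
        assert (thr.maf_min, thr.call_rate_min, thr.hwe_p_min) == (0.05, 0.95, 0.001)

    def test_idempotent(self, rng):
        codes = rng.binomial(2, rng.uniform(0.1, 0.5, 30), size=(50, 30))
        g = GenotypeMatrix(codes=codes)
        once, kept1 = qc_filter(g)
        twice, kept2 = qc_filter(once)
        assert np.array_equal(once.codes, twice.codes)
        assert len(kept2) == once.n_snps

    def test_all_removed_raises_empty_panel(self):
        g = GenotypeMatrix(codes=np.zeros((4, 3), dtype=int))
        with pytest.raises(ValueError, match="empty panel"):
            qc_filter(g)

    def test_all_missing_snp_removed_without_division_error(self):
        col_missing = np.full(20, MISSING)
        g = GenotypeMatrix(codes=np.column_stack([_hw_column(20), col_missing]))
        _, kept = qc_filter(g)
        assert list(kept) == [0]


class TestGRM:
    def test_single_snp_closed_form(self):
        g = GenotypeMatrix(codes=np.array([[0], [2]]))
        rel = compute_grm(g)
        assert np.allclose(rel.A, [[2.0, -2.0], [-2.0, 2.0]])

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(5):
            codes = rng.binomial(2, rng.uniform(0.2, 0.8, 50), size=(5, 50))
            if np.any(allele_frequencies(codes) % 1 == 0):
                continue
            g = GenotypeMatrix(codes=codes)
            rel = compute_grm(g)
            p = allele_frequencies(codes)
            denom = np.sum(2 * p * (1 - p))
            n = codes.shape[0]
            expected = np.zeros((n, n))
            for i in range(n):
                for k in range(n):
                    expected[i, k] = sum(
                        (codes[i, j] - 2 * p[j]) * (codes[k, j] - 2 * p[j])
                        for j in range(codes.shape[1])
                    ) / denom
            assert np.abs(rel.A - expected).max() <= 1e-12

    def test_mean_diagonal_near_one_under_hardy_weinberg(self, rng):
        p = rng.uniform(0.1, 0.5, 5000)
        codes = rng.binomial(2, p, size=(40, 5000))
        rel = compute_grm(GenotypeMatrix(codes=codes))
        assert abs(np.mean(np.diag(rel.A)) - 1.0) < 0.05

    def test_invariant_to_snp_permutation(self, rng):
        codes = rng.binomial(2, rng.uniform(0.2, 0.5, 100), size=(10, 100))
        g = GenotypeMatrix(codes=codes)
        perm = rng.permutation(100)
        g_perm = GenotypeMatrix(codes=codes[:, perm])
        assert np.abs(compute_grm(g).A - compute_grm(g_perm).A).max() <= 1e-12

    def test_missing_imputed_to_snp_mean(self):
        codes = np.array([[0, 1], [2, 1], [1, MISSING], [1, 0]])
        rel = compute_grm(GenotypeMatrix(codes=codes))
        # the missing entry contributes m_ij = 0 to every product
        p = allele_frequencies(codes)
        M = np.where(codes == MISSING, 0.0, codes - 2 * p)
        expected = M @ M.T / np.sum(2 * p * (1 - p))
        assert np.allclose(rel.A, expected)

    def test_monomorphic_raises_with_snp_name(self):
        g = GenotypeMatrix(
            codes=np.array([[0, 1], [0, 1], [0, 2]]), snp_ids=["mono", "ok"]
        )
        with pytest.raises(ValueError, match="mono"):
            compute_grm(g)


class TestCholeskyPSD:
    def test_identity_no_jitter(self):
        L, jitter = cholesky_psd(np.eye(4))
        assert jitter == 0.0
        assert np.allclose(L, np.eye(4))

    def test_rank_deficient_needs_jitter(self, rng):
        v = rng.standard_normal(4)
        A = np.outer(v, v)
        L, jitter = cholesky_psd(A)
        assert jitter > 0
        recon = L @ L.T
        rel_err = np.linalg.norm(recon - A) / np.linalg.norm(A)
        assert rel_err <= 1e-6

    def test_spd_exact(self, rng):
        B = rng.standard_normal((6, 6))
        A = B @ B.T + np.eye(6)
        L, jitter = cholesky_psd(A)
        assert jitter == 0.0
        assert np.linalg.norm(L @ L.T - A) / np.linalg.norm(A) <= 1e-10

    def test_indefinite_raises_with_eigenvalue(self):
        A = np.diag([1.0, -2.0])
        with pytest.raises(np.linalg.LinAlgError, match="eigenvalue"):
            cholesky_psd(A)


class TestSyntheticGenotypes:
    def test_fixed_half_frequency(self):
        g = synthetic_genotypes(1000, 50, maf_low=0.5, maf_high=0.5, seed=1)
        p_hat = allele_frequencies(g.codes)
        assert np.abs(p_hat - 0.5).max() < 0.05

    def test_empirical_frequencies_match_drawn(self):
        g = synthetic_genotypes(800, 200, seed=2)
        p_hat = allele_frequencies(g.codes)
        p = g.true_frequencies
        se = np.sqrt(p * (1 - p) / (2 * 800))
        assert np.mean(np.abs(p_hat - p) < 4 * se + 1e-9) > 0.99

    def test_full_sib_families_show_in_grm(self):
        n, fam = 60, 12
        g = synthetic_genotypes(n, 3000, n_families=fam, seed=3)
        g, _ = qc_filter(g)
        A = compute_grm(g).A
        size = n // fam
        within, between = [], []
        groups = [range(f * size, (f + 1) * size) for f in range(fam)]
        for f, idx in enumerate(groups):
            for i in idx:
                for j in idx:
                    if i < j:
                        within.append(A[i, j])
            for i in idx:
                for j in range(n):
                    if j not in idx:
                        between.append(A[i, j])
        assert abs(np.mean(within) - 0.5) < 0.1
        assert abs(np.mean(between)) < 0.1

    def test_too_many_families_raises(self):
        with pytest.raises(ValueError, match="families"):
            synthetic_genotypes(5, 10, n_families=3)

    def test_deterministic_given_seed(self):
        a = synthetic_genotypes(30, 40, seed=9)
        b = synthetic_genotypes(30, 40, seed=9)
        assert np.array_equal(a.codes, b.codes)


def test_hwe_pvalue_detects_excess_heterozygosity():
    het = np.ones((100, 1), dtype=int)
    assert hwe_pvalues(het)[0] < 1e-10
    hw = _hw_column(100)[:, None]
    assert hwe_pvalues(hw)[0] > 0.9
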