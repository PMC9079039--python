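"""Paired tests, reliability, and permutation 1-D SPM."""

import numpy as np
import pytest
from scipy import stats as sps

from kneefe.stats import (
    DegenerateSampleError,
    find_clusters,
    icc_intra_rater,
    paired_t_ci,
    shapiro_wilk,
    spm_paired_t,
    spm_paired_test,
    spm_threshold_permutation,
)


class TestShapiroWilk:
    def test_constant_sample_flagged(self):
        with pytest.raises(DegenerateSampleError):
            shapiro_wilk(np.ones(20))

    def test_exponential_sample_rejected(self):
        rng = np.random.default_rng(3)
        w, p = shapiro_wilk(rng.exponential(1.0, 50))
        assert p < 0.01

    def test_type_one_error_rate_near_alpha(self):
        # normal data: rejection rate at alpha=0.05 within [0.03, 0.07]
        rejections = 0
        n_rep = 500
        rng = np.random.default_rng(77)
        for _ in range(n_rep):
            _, p = shapiro_wilk(rng.normal(size=500))
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestPairedT:
    def test_identical_vectors(self):
        x = np.arange(10.0)
        r = paired_t_ci(x, x)
        assert r.degenerate
        assert r.t == 0.0 and r.ci_low == r.ci_high == 0.0

    def test_constant_shift_with_jitter(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 30)
        b = a - 2.0 + rng.normal(0, 1e-6, 30)
        r = paired_t_ci(a, b)
        assert r.ci_low < 2.0 < r.ci_high

    def test_closed_form_five_pairs(self):
        # textbook-style worked example via the closed formula
        a = np.array([12.0, 15.0, 11.0, 16.0, 14.0])
        b = np.array([10.0, 14.0, 11.0, 12.0, 13.0])
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        r = paired_t_ci(a, b)
        assert r.t == pytest.approx(t_hand, rel=1e-12)
        ref = sps.ttest_rel(a, b)
        assert r.t == pytest.approx(ref.statistic)
        assert r.p == pytest.approx(ref.pvalue)


class TestICC:
    def test_perfect_consistency(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 3, 30)
        x = np.tile(base[:, None], (1, 3))
        assert icc_intra_rater(x).icc == pytest.approx(1.0, abs=1e-9)

    def test_null_noise_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (200, 3))  # no subject effect
        assert abs(icc_intra_rater(x).icc) < 0.1

    def test_anova_closed_form(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (12, 3)) + rng.normal(0, 2, (12, 1))
        r = icc_intra_rater(x)
        # independent oracle: the ICC(3,1) formula from the ANOVA table
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = (((x - grand) ** 2).sum() - msr * (n - 1) - msc * (k - 1)) / ((n - 1) * (k - 1))
        assert r.icc == pytest.approx((msr - mse) / (msr + (k - 1) * mse), rel=1e-12)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            icc_intra_rater(np.ones((3, 3)))


class TestSPMPointwise:
    def test_identical_trajectories_give_zero(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(6, 50))
        np.testing.assert_array_equal(spm_paired_t(a, a.copy()), 0.0)

    def test_constant_offset_sign(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(10, 50))
        b = a - 0.8 + rng.normal(0, 0.1, size=(10, 50))
        t = spm_paired_t(a, b)
        assert np.all(t > 0)

    def test_pointwise_equals_paired_t(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(9, 20))
        b = rng.normal(size=(9, 20))
        t = spm_paired_t(a, b)
        for j in range(20):
            assert t[j] == pytest.approx(paired_t_ci(a[:, j], b[:, j]).t, rel=1e-12)

    def test_invariant_to_common_subject_shift(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(8, 30))
        b = rng.normal(size=(8, 30))
        shift = rng.normal(0, 5, size=(8, 1))
        np.testing.assert_allclose(spm_paired_t(a + shift, b + shift), spm_paired_t(a, b))


class TestSPMThreshold:
    def test_exhaustive_for_three_subjects(self):
        rng = np.random.default_rng(8)
        d = rng.normal(size=(3, 25))
        t1 = spm_threshold_permutation(d, n_permutations=1000, seed=1)
        t2 = spm_threshold_permutation(d, n_permutations=1000, seed=99)
        assert t1 == t2  # 2^3 = 8 <= budget: exhaustive, seed-independent

    def test_seed_reproducibility_when_sampled(self):
        rng = np.random.default_rng(9)
        d = rng.normal(size=(25, 40))
        t1 = spm_threshold_permutation(d, n_permutations=300, seed=5)
        t2 = spm_threshold_permutation(d, n_permutations=300, seed=5)
        assert t1 == t2

    def test_exhaustive_agrees_with_large_sample(self):
        rng = np.random.default_rng(10)
        d = rng.normal(size=(8, 30))
        exact = spm_threshold_permutation(d, n_permutations=300, seed=0)  # 2^8=256 exhaustive
        sampled = spm_threshold_permutation(d, n_permutations=20000, seed=3)
        assert sampled == pytest.approx(exact, rel=0.05)


class TestClusters:
    def test_no_clusters_for_zero_or_high_threshold(self):
        assert find_clusters(np.zeros(50), 1.0) == []
        t = np.sin(np.linspace(0, np.pi, 50))
        assert find_clusters(t, 2.0) == []

    def test_single_interval(self):
        q = np.linspace(0, 100, 101)
        t = np.where((q >= 40) & (q <= 60), 5.0, 0.0)
        clusters = find_clusters(t, 2.0, q)
        assert len(clusters) == 1
        assert clusters[0].start_pct == 40.0
        assert clusters[0].end_pct == 60.0

    def test_full_test_on_identical_data_reports_nothing(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=(8, 40))
        res = spm_paired_test(a, a.copy(), n_permutations=200, seed=1)
        assert res.clusters == ()

    def test_nan_grid_points_excluded_pairwise(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=(8, 40))
        b = rng.normal(size=(8, 40))
        a[0, 5] = np.nan
        res = spm_paired_test(a, b, n_permutations=200, seed=1)
        assert len(res.stance_pct) == 39
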