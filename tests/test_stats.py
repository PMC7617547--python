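"""Inferential layer: binomial overlap, cluster permutation, FDR, Cook's screen."""

import math

import numpy as np
import pytest

from tremornet.datatypes import ROI_LABELS
from tremornet.stats import (
    bh_fdr,
    binomial_overlap_p,
    cluster_permutation,
    cooks_screened_correlation,
    overlap_map,
    quartile_split_test,
)


def _binom_tail_bruteforce(k, n, p):
    """Enumerate the binomial mass function directly."""
    total = 0.0
    for j in range(k, n + 1):
        total += math.comb(n, j) * p**j * (1 - p) ** (n - j)
    return total


class TestBinomialOverlap:
    def test_matches_bruteforce_enumeration(self):
        for n in range(1, 13):
            for k in range(0, n + 1):
                assert binomial_overlap_p(k, n, 0.15) == pytest.approx(
                    _binom_tail_bruteforce(k, n, 0.15), abs=1e-12
                )

    @pytest.mark.parametrize(
        "k, n, expected",
        [(5, 11, 0.016), (6, 11, 0.003), (1, 4, 0.478), (2, 4, 0.110),
         (3, 4, 0.012), (4, 4, 0.001)],
    )
    def test_reference_overlap_probabilities(self, k, n, expected):
        assert round(binomial_overlap_p(k, n, 0.15), 3) == expected

    def test_k_zero_is_certain(self):
        assert binomial_overlap_p(0, 7, 0.15) == 1.0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            binomial_overlap_p(5, 4, 0.15)
        with pytest.raises(ValueError):
            binomial_overlap_p(1, 4, 1.5)


class TestOverlapMap:
    def test_common_peak_counts_all_subjects(self):
        rng = np.random.default_rng(0)
        maps = rng.uniform(0, 1, (8, 10))
        maps[:, 3] = 10.0  # everyone peaks at ROI 3
        res = overlap_map(maps, ROI_LABELS, percentile=85)
        assert res.counts[3] == 8
        assert res.p_binom[3] == pytest.approx(0.15**8, rel=1e-6)

    def test_percentile_arithmetic_on_twenty_rois(self):
        rng = np.random.default_rng(1)
        labels = tuple(f"roi{i}" for i in range(20))
        maps = rng.uniform(size=(5, 20))
        res = overlap_map(maps, labels, percentile=85)
        # 15% of 20 ROIs = 3 suprathreshold entries per subject
        assert res.counts.sum() == 5 * 3

    def test_counts_calibrated_under_independence(self):
        rng = np.random.default_rng(2)
        totals = []
        for _ in range(200):
            maps = rng.uniform(size=(10, 20))
            totals.append(overlap_map(maps, tuple(f"r{i}" for i in range(20))).counts.mean())
        # mean count per ROI ~ N * 0.15
        assert np.mean(totals) == pytest.approx(10 * 0.15, rel=0.05)

    def test_constant_subject_contributes_nothing(self):
        maps = np.ones((3, 10))
        maps[0] = np.arange(10)
        res = overlap_map(maps, ROI_LABELS)
        # only the non-constant subject contributes: values 8 and 9 exceed
        # the 85th percentile of 0..9
        assert res.counts.sum() == 2


class TestClusterPermutation:
    def test_identical_groups_produce_no_significant_cluster(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((8, 40))
        res = cluster_permutation(a, a.copy(), n_perm=200, seed=4)
        assert not res.significant()

    def test_strong_sustained_offset_detected(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((12, 50))
        b = rng.standard_normal((11, 50))
        a[:, 10:25] += 2.0
        res = cluster_permutation(a, b, n_perm=500, seed=6)
        assert res.significant()
        start, stop = res.clusters[int(np.argmin(res.p_values))]
        assert start >= 5 and stop <= 30

    def test_p_never_zero(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((10, 30)) + 5.0
        b = rng.standard_normal((10, 30))
        res = cluster_permutation(a, b, n_perm=100, seed=8)
        assert np.all(res.p_values >= 1.0 / 101)

    def test_relabelling_symmetry(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal((9, 30))
        b = rng.standard_normal((8, 30)) + 0.8
        res_ab = cluster_permutation(a, b, n_perm=400, seed=10)
        res_ba = cluster_permutation(b, a, n_perm=400, seed=10)
        np.testing.assert_allclose(np.abs(res_ab.t_obs), np.abs(res_ba.t_obs), atol=1e-10)
        assert res_ab.clusters == res_ba.clusters

    def test_paired_sign_flip_detects_consistent_difference(self):
        rng = np.random.default_rng(11)
        b = rng.standard_normal((10, 40))
        a = b + 0.1 * rng.standard_normal((10, 40))
        a[:, 5:20] += 1.0
        res = cluster_permutation(a, b, paired=True, n_perm=500, seed=12)
        assert res.significant()

    def test_zero_variance_rejected(self):
        a = np.ones((5, 20))
        with pytest.raises(ValueError, match="variance"):
            cluster_permutation(a, a, paired=True, n_perm=50, seed=13)

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(ValueError, match=">= 3"):
            cluster_permutation(rng.standard_normal((2, 10)),
                                rng.standard_normal((5, 10)), n_perm=50)

    def test_familywise_error_roughly_calibrated(self):
        # light version of the full calibration (acceptance runs 500 reps)
        rng = np.random.default_rng(15)
        hits = 0
        for _ in range(100):
            a = rng.standard_normal((8, 40))
            b = rng.standard_normal((8, 40))
            res = cluster_permutation(a, b, n_perm=200, seed=rng)
            hits += bool(res.p_values.size and res.p_values.min() <= 0.05)
        assert hits <= 12  # ~binomial(100, 0.05) upper tail


class TestQuartileSplit:
    def test_eight_trials_two_per_quartile(self):
        rng = np.random.default_rng(16)
        values = np.arange(8.0)
        latents = np.zeros((8, 20))
        latents[values >= 6] = 1.0  # top quartile trials (6, 7) carry a signal
        lat = {f"s{i}": latents + 0.01 * rng.standard_normal((8, 20)) for i in range(6)}
        val = {f"s{i}": values for i in range(6)}
        res = quartile_split_test(lat, val, n_perm=300, seed=17)
        # top-vs-bottom mean difference ~1 across all subjects: one big cluster
        assert res.significant()
        assert res.t_obs.mean() > 0

    def test_values_independent_of_latents_yield_no_cluster(self):
        rng = np.random.default_rng(18)
        lat = {f"s{i}": rng.standard_normal((16, 20)) for i in range(8)}
        val = {f"s{i}": rng.standard_normal(16) for i in range(8)}
        res = quartile_split_test(lat, val, n_perm=300, seed=19)
        assert not res.significant()

    def test_too_few_trials_rejected(self):
        lat = {"s0": np.zeros((5, 10))}
        val = {"s0": np.arange(5.0)}
        with pytest.raises(ValueError, match="8 trials"):
            quartile_split_test(lat, val)


class TestBhFdr:
    def test_step_up_against_direct_oracle(self):
        pvals = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205,
                          0.212, 0.216, 0.222, 0.251, 0.269, 0.275, 0.34, 0.341])
        # direct step-up: largest i with p_(i) <= i/m * q
        m = len(pvals)
        order = np.sort(pvals)
        thresh = [i / m * 0.05 for i in range(1, m + 1)]
        passing = [i for i in range(m) if order[i] <= thresh[i]]
        k = max(passing) + 1 if passing else 0
        expected = pvals <= (order[k - 1] if k else 0.0)
        rejected, adjusted = bh_fdr(pvals, q=0.05)
        np.testing.assert_array_equal(rejected, expected)
        assert np.all(np.diff(adjusted[np.argsort(pvals)]) >= -1e-12)

    def test_all_ones_rejects_nothing(self):
        rejected, _ = bh_fdr(np.ones(5))
        assert not rejected.any()

    def test_single_small_p_rejected(self):
        rejected, adjusted = bh_fdr(np.array([0.01]), q=0.05)
        assert rejected[0] and adjusted[0] == pytest.approx(0.01)

    def test_empty_input_empty_output(self):
        rejected, adjusted = bh_fdr(np.array([]))
        assert rejected.size == 0 and adjusted.size == 0

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.0, 0.5]))


class TestCooksScreen:
    def test_gross_outlier_removed_restores_fit(self):
        rng = np.random.default_rng(20)
        x = np.linspace(0, 1, 20)
        y = 2 * x + 0.001 * rng.standard_normal(20)
        y[7] = 10.0
        res = cooks_screened_correlation(x, y)
        assert 7 in res["removed"]
        assert res["r2"] > 0.999

    def test_perfect_line_removes_nothing(self):
        x = np.linspace(0, 1, 10)
        res = cooks_screened_correlation(x, 3 * x + 1)
        assert res["removed"].size == 0
        assert res["r2"] == pytest.approx(1.0)

    def test_no_point_above_threshold_means_no_removal(self):
        rng = np.random.default_rng(21)
        x = rng.standard_normal(30)
        y = x + 0.3 * rng.standard_normal(30)
        res = cooks_screened_correlation(x, y, multiplier=1e6)
        assert res["removed"].size == 0
        assert not res["unreliable"]

    def test_clean_noise_removes_few_points(self):
        rng = np.random.default_rng(22)
        x = rng.standard_normal(30)
        y = x + 0.3 * rng.standard_normal(30)
        res = cooks_screened_correlation(x, y)
        assert res["removed"].size <= 5
        assert res["r2"] > 0.5

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cooks_screened_correlation(np.arange(3.0), np.arange(3.0))
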