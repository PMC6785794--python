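"""Nonparametric dose-response statistics with exact small-sample p values."""

import itertools
import math

import numpy as np
import pytest

from bmdosim.cohort_stats import (
    dose_response_analysis,
    dose_response_grid,
    group_comparisons,
    relative_platelet_nadir,
    spearman_correlation,
    wilcoxon_rank_sum,
)
from bmdosim.synthetic import CohortSpec, simulate_cohort


class TestRelativeNadir:
    def test_half_and_full(self):
        assert relative_platelet_nadir(241.0, 120.5) == pytest.approx(0.5)
        assert relative_platelet_nadir(200.0, 200.0) == 1.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            relative_platelet_nadir(0.0, 100.0)


def spearman_exact_oracle(x, y):
    """Independent enumeration via the sum-of-squared-rank-differences form
    (valid without ties): r = 1 - 6 sum d^2 / (n (n^2 - 1))."""
    n = len(x)
    rx = np.argsort(np.argsort(x)) + 1.0
    ry = np.argsort(np.argsort(y)) + 1.0
    r_obs = 1 - 6 * np.sum((rx - ry) ** 2) / (n * (n**2 - 1))
    count = total = 0
    for perm in itertools.permutations(ry):
        r = 1 - 6 * np.sum((rx - np.array(perm)) ** 2) / (n * (n**2 - 1))
        total += 1
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
    return r_obs, count / total


class TestSpearman:
    def test_reversed_ranks(self):
        r, _ = spearman_correlation([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_worked_five_point_example(self):
        # sum d^2 = 8 -> r = 1 - 48/120 = 0.6
        r, p = spearman_correlation([1, 2, 3, 4, 5], [3, 1, 2, 5, 4])
        assert r == pytest.approx(0.6)
        _, p_oracle = spearman_exact_oracle([1, 2, 3, 4, 5], [3, 1, 2, 5, 4])
        assert p == pytest.approx(p_oracle)

    def test_perfect_monotone_exact_p(self):
        _, p = spearman_correlation([1, 2, 3, 4, 5], [2, 3, 5, 8, 13])
        assert p == pytest.approx(2 / 120)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_p_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(3):
            x = rng.permutation(n) + rng.uniform(0, 0.01, n)
            y = rng.permutation(n) + rng.uniform(0, 0.01, n)
            r, p = spearman_correlation(x, y)
            r_o, p_o = spearman_exact_oracle(x, y)
            assert r == pytest.approx(r_o, abs=1e-9)
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_large_n_matches_scipy_t_approximation(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        r, p = spearman_correlation(x, y)
        r_s, p_s = stats.spearmanr(x, y)
        assert r == pytest.approx(r_s, abs=1e-12)
        assert p == pytest.approx(p_s, rel=1e-6)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(1, 10, 8)
        y = rng.uniform(1, 10, 8)
        r0, p0 = spearman_correlation(x, y)
        r1, p1 = spearman_correlation(np.exp(x), y**3)
        assert (r1, p1) == (pytest.approx(r0), pytest.approx(p0))

    def test_antisymmetry_under_negation(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 7)
        y = rng.uniform(0, 1, 7)
        assert spearman_correlation(x, y)[0] == pytest.approx(
            -spearman_correlation(x, -y)[0]
        )

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="zero rank variance"):
            spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])


def ranksum_exact_oracle(a, b):
    """Independent enumeration over label assignments of the pooled sample."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    mean_w = n_a * ranks.mean()
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            hits += 1
    return w_obs, hits / total


class TestWilcoxonRankSum:
    def test_worked_example(self):
        w, p = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0, 5.0])
        assert w == 3.0
        assert p == pytest.approx(0.2)

    def test_identical_singletons(self):
        _, p = wilcoxon_rank_sum([1.0], [1.0])
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_p_matches_enumeration_for_all_small_splits(self):
        rng = np.random.default_rng(9)
        for n in range(2, 9):
            for n_a in range(1, n):
                x = rng.uniform(0, 10, n)
                x[rng.integers(n)] = x[rng.integers(n)]  # occasional tie
                a, b = x[:n_a], x[n_a:]
                w, p = wilcoxon_rank_sum(a, b)
                w_o, p_o = ranksum_exact_oracle(a, b)
                assert w == pytest.approx(w_o)
                assert p == pytest.approx(p_o, abs=1e-12)

    def test_large_sample_normal_approximation_is_sane(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30)
        b = rng.normal(1.5, 1, 30)
        _, p = wilcoxon_rank_sum(a, b)
        assert p < 1e-4
        _, p_null = wilcoxon_rank_sum(a, rng.normal(0, 1, 30))
        assert p_null > 0.01


class TestDoseResponse:
    def test_zero_noise_monotone_cohort_is_perfectly_correlated(self):
        records, _ = simulate_cohort(CohortSpec.monotone_zero_noise(n_patients=12, seed=5))
        grid = dose_response_grid(records)
        usable = grid[grid.n >= 3]
        assert len(usable) > 0
        assert np.allclose(usable.r_s, -1.0)

    def test_insufficient_group_flagged_not_significant(self):
        records, _ = simulate_cohort(CohortSpec(n_patients=2, seed=0))
        res = dose_response_analysis(records, "planar", 1, "all")
        assert math.isnan(res.r_s)
        assert not res.significant

    def test_groups_partition_the_cohort(self):
        records, _ = simulate_cohort(CohortSpec(n_patients=30, seed=7))
        res_all = dose_response_analysis(records, "planar", 1, "all")
        res_with = dose_response_analysis(records, "planar", 1, "with_mets")
        res_without = dose_response_analysis(records, "planar", 1, "without_mets")
        assert res_all.n == res_with.n + res_without.n

    def test_default_cohort_fraction2_is_significant(self):
        # under default noise the cumulative-dose correlation is strongly
        # negative after the second fraction
        records, _ = simulate_cohort(CohortSpec(seed=1))
        res = dose_response_analysis(records, "V_SPECT", 2, "all")
        assert res.r_s < 0
        assert res.p_value < 0.05

    def test_group_comparisons_table_shape(self):
        records, _ = simulate_cohort(CohortSpec(seed=3))
        table = group_comparisons(records)
        assert "l1_l4_concentration_male_vs_female" in set(table.comparison)
        assert {"statistic", "p_value", "significant"} <= set(table.columns)
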