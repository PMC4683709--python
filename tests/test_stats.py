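"""Resampling, exact adjacency null, and classical test wrappers."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from intronevo.loss_features import adjacent_loss_pairs
from intronevo.stats import (
    IntronPool,
    adjacency_null_distribution,
    chi_square_2x2,
    mann_whitney_u,
    resample_adjacent_pairs,
    wilcoxon_signed_rank,
)


def enumerate_null(n, k):
    """Exact adjacent-pair distribution by enumerating all C(n, k) subsets."""
    counts = {}
    for subset in itertools.combinations(range(1, n + 1), k):
        pairs = adjacent_loss_pairs({"g": list(subset)})
        counts[pairs] = counts.get(pairs, 0) + 1
    total = sum(counts.values())
    out = np.zeros(max(counts) + 1)
    for j, c in counts.items():
        out[j] = c / total
    return out


class TestAdjacencyNull:
    def test_two_of_two_always_one_pair(self):
        null = adjacency_null_distribution([(2, 2)])
        assert null.total == pytest.approx([0.0, 1.0])

    def test_two_of_three(self):
        null = adjacency_null_distribution([(3, 2)])
        assert null.total == pytest.approx([1 / 3, 2 / 3])

    def test_convolution_of_two_genes(self):
        null = adjacency_null_distribution([(3, 2), (3, 2)])
        assert null.total == pytest.approx([1 / 9, 4 / 9, 4 / 9])

    def test_dp_equals_enumeration_exhaustively(self):
        """DP distribution equals brute-force enumeration for all n <= 8."""
        for n in range(1, 9):
            for k in range(0, n + 1):
                dp = adjacency_null_distribution([(n, k)]).total
                brute = enumerate_null(n, k)
                m = max(len(dp), len(brute))
                dp = np.pad(dp, (0, m - len(dp)))
                brute = np.pad(brute, (0, m - len(brute)))
                np.testing.assert_allclose(dp, brute, atol=1e-12, err_msg=f"n={n} k={k}")

    def test_distribution_sums_to_one_and_tail(self):
        null = adjacency_null_distribution([(5, 3), (7, 2), (4, 4)], observed=2)
        assert null.total.sum() == pytest.approx(1.0, abs=1e-9)
        assert 0 <= null.tail_p <= 1
        assert adjacency_null_distribution([(3, 2)], observed=5).tail_p == 0.0

    def test_k_greater_than_n_is_error(self):
        with pytest.raises(ValueError):
            adjacency_null_distribution([(3, 4)])


class TestResampling:
    def test_isolated_introns_never_pair(self):
        pool = IntronPool([(f"g{i}", 1) for i in range(20)], n_lost=5)
        res = resample_adjacent_pairs(pool, observed=0, R=200, seed=1)
        assert res.p_value == 1.0
        res1 = resample_adjacent_pairs(pool, observed=1, R=200, seed=1)
        assert res1.p_value == 0.0

    def test_matches_exact_enumeration_within_3_sigma(self):
        # one gene with 3 introns, 2 lost: P(1 pair) = 2/3 exactly
        pool = IntronPool([("g", 1), ("g", 2), ("g", 3)], n_lost=2)
        R = 10_000
        res = resample_adjacent_pairs(pool, observed=1, R=R, seed=3)
        p_exact = 2 / 3
        sigma = math.sqrt(p_exact * (1 - p_exact) / R)
        assert abs(res.p_value - p_exact) < 3 * sigma

    def test_converges_to_dp_tail_on_single_gene_pool(self):
        pool = IntronPool([("g", i) for i in range(1, 8)], n_lost=3)
        null = adjacency_null_distribution([(7, 3)], observed=1)
        R = 4000
        res = resample_adjacent_pairs(pool, observed=1, R=R, seed=5)
        sigma = math.sqrt(null.tail_p * (1 - null.tail_p) / R)
        assert abs(res.p_value - null.tail_p) < 3 * sigma

    def test_seeded_reproducibility(self):
        pool = IntronPool([("g", i) for i in range(1, 30)], n_lost=10)
        a = resample_adjacent_pairs(pool, observed=3, R=500, seed=42)
        b = resample_adjacent_pairs(pool, observed=3, R=500, seed=42)
        assert a.tail_count == b.tail_count and a.p_value == b.p_value

    def test_negative_observed_is_error(self):
        pool = IntronPool([("g", 1)], n_lost=1)
        with pytest.raises(ValueError):
            resample_adjacent_pairs(pool, observed=-1)

    def test_shrunk_estimator(self):
        pool = IntronPool([(f"g{i}", 1) for i in range(10)], n_lost=2)
        res = resample_adjacent_pairs(pool, observed=1, R=99, seed=0)
        assert res.p_value == 0.0
        assert res.p_value_shrunk == pytest.approx(1 / 100)


class TestChiSquare:
    def test_no_association(self):
        chi2, p = chi_square_2x2(10, 100, 10, 100)
        assert chi2 == 0 and p == 1

    def test_scalar_formula_oracle(self):
        a, b, c, d = 20, 80, 10, 90
        chi2, p = chi_square_2x2(a, b, c, d)
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(expected)

    def test_row_and_column_swap_invariance(self):
        base = chi_square_2x2(30, 70, 10, 90)
        assert chi_square_2x2(10, 90, 30, 70) == pytest.approx(base)
        assert chi_square_2x2(70, 30, 90, 10) == pytest.approx(base)

    def test_zero_margin_warns_p_one(self):
        chi2, p = chi_square_2x2(0, 0, 5, 10)
        assert chi2 == 0 and p == 1


class TestMannWhitney:
    def test_small_exact_example(self):
        U, p = mann_whitney_u([1, 2], [3, 4])
        assert U == 0 and p == pytest.approx(1 / 3)

    def test_identical_multisets_p_one(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_small_samples_take_the_exact_path(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=8)
        y = rng.normal(loc=0.5, size=8)
        _, p_exact = sps.mannwhitneyu(x, y, method="exact")
        _, p_ours = mann_whitney_u(x, y)
        assert p_ours == pytest.approx(p_exact)

    def test_asymptotic_path_close_to_exact(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=9)
        y = rng.normal(loc=0.5, size=9)
        _, p_exact = sps.mannwhitneyu(x, y, method="exact")
        _, p_ours = mann_whitney_u(x, y)  # n > 8: normal approximation
        assert abs(p_ours - p_exact) < 2e-2

    def test_constant_samples(self):
        _, p = mann_whitney_u([1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0


class TestWilcoxon:
    def test_all_below_half_one_sided(self):
        positions = np.linspace(0.05, 0.45, 10)
        p = wilcoxon_signed_rank(positions, alternative="less")
        assert p == pytest.approx(2**-10)

    def test_symmetric_pair_p_one(self):
        assert wilcoxon_signed_rank([0.4, 0.6]) == pytest.approx(1.0)

    def test_all_at_median_p_one(self):
        assert wilcoxon_signed_rank([0.5, 0.5, 0.5]) == 1.0

    def test_exact_vs_approx_agree_at_n20(self):
        rng = np.random.default_rng(7)
        d = rng.uniform(0.2, 0.8, size=20)
        p_exact = float(sps.wilcoxon(d - 0.5, method="exact").pvalue)
        p_approx = float(sps.wilcoxon(d - 0.5, method="approx", correction=True).pvalue)
        assert abs(p_exact - p_approx) < 1e-2
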