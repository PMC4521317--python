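"""Entropy, mutual information and conditional entropy estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icuinfo.infotheory import (
    conditional_entropy,
    decompose,
    empirical_distribution,
    entropy,
    joint_distribution,
    mutual_information,
    oracle_mi,
)


class TestEmpiricalDistribution:
    @pytest.mark.parametrize(
        "indices, n_bins, expected",
        [
            ([0, 0, 1, 1], 2, [0.5, 0.5]),
            ([3], 20, [0.0] * 3 + [1.0] + [0.0] * 16),
            (list(range(20)), 20, [0.05] * 20),
        ],
    )
    def test_counting(self, indices, n_bins, expected):
        np.testing.assert_allclose(empirical_distribution(indices, n_bins), expected)

    def test_rejects_empty_and_out_of_range(self):
        with pytest.raises(ValueError):
            empirical_distribution([], 5)
        with pytest.raises(ValueError):
            empirical_distribution([5], 5)


class TestEntropy:
    @pytest.mark.parametrize(
        "dist, expected",
        [
            (np.full(20, 0.05), math.log2(20)),  # uniform 20 bins: 4.32 bits
            ([0.5, 0.5], 1.0),
            ([0.9, 0.1], 0.4689955935892812),  # biased coin, direct evaluation
            ([1.0, 0.0, 0.0], 0.0),
        ],
    )
    def test_known_values(self, dist, expected):
        assert entropy(dist) == pytest.approx(expected, abs=1e-12)

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            entropy([0.5, 0.4])


class TestMutualInformation:
    def test_independent_joint_is_zero(self):
        px = np.array([0.2, 0.3, 0.5])
        py = np.array([0.6, 0.4])
        assert mutual_information(np.outer(px, py)) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 5, 20])
    def test_perfect_dependence_equals_log2_k(self, k):
        assert mutual_information(np.eye(k) / k) == pytest.approx(math.log2(k), abs=1e-12)

    def test_asymmetric_2x2(self):
        # 0.8*log2(1.6) + 0.2*log2(0.4), evaluated independently
        joint = np.array([[0.4, 0.1], [0.1, 0.4]])
        assert mutual_information(joint) == pytest.approx(0.27807190511263774, abs=1e-12)

    def test_joint_distribution_counting(self):
        pairs = [(0, 0)] * 4 + [(0, 1), (1, 0)] + [(1, 1)] * 4
        joint = joint_distribution([p[0] for p in pairs], [p[1] for p in pairs], 2, 2)
        np.testing.assert_allclose(joint, [[0.4, 0.1], [0.1, 0.4]])

    def test_symmetry_under_transpose(self, rng):
        for _ in range(50):
            table = rng.dirichlet(np.ones(12)).reshape(3, 4)
            assert mutual_information(table) == pytest.approx(
                mutual_information(table.T), abs=1e-12
            )


class TestOracleAgreement:
    def test_oracle_matches_estimator_on_random_tables(self, rng):
        """Independent double-loop evaluation agrees on 1000+ random joints."""
        for _ in range(1000):
            nx = int(rng.integers(2, 21))
            ny = int(rng.integers(2, 21))
            table = rng.dirichlet(np.ones(nx * ny)).reshape(nx, ny)
            assert abs(mutual_information(table) - oracle_mi(table)) < 1e-12

    def test_oracle_trivial_tables(self):
        assert oracle_mi(np.eye(4) / 4) == pytest.approx(2.0, abs=1e-12)
        outer = np.outer([0.3, 0.7], [0.5, 0.5])
        assert oracle_mi(outer) == pytest.approx(0.0, abs=1e-12)


class TestConditionalEntropy:
    @pytest.mark.parametrize(
        "h_x, mi, expected",
        [
            (4.32, 4.32, 0.0),
            (2.5, 0.0, 2.5),
            (1.0, 0.27807190511263774, 0.7219280948873623),
        ],
    )
    def test_subtraction(self, h_x, mi, expected):
        assert conditional_entropy(h_x, mi) == pytest.approx(expected, abs=1e-12)

    def test_rejects_mi_exceeding_entropy(self):
        with pytest.raises(ValueError):
            conditional_entropy(1.0, 1.5)


class TestDecompose:
    def test_identical_streams_fully_redundant(self):
        x = [0, 1, 2, 3] * 25
        d = decompose(x, x, 20)
        assert d.mi == pytest.approx(d.h_x, abs=1e-12)
        assert d.h_x_given_y == pytest.approx(0.0, abs=1e-12)
        assert d.n_pairs == 100

    def test_single_pair_value_all_zero(self):
        d = decompose([7, 7, 7], [2, 2, 2], 20)
        assert d.h_x == d.h_y == d.mi == 0.0

    def test_independent_streams_mi_at_bias_level(self, rng):
        n = 100_000
        x = rng.integers(0, 20, n)
        y = rng.integers(0, 20, n)
        bias = 19 * 19 / (2 * n * math.log(2))
        assert decompose(x, y, 20).mi <= 0.01 + bias

    def test_miller_madow_reduces_independent_mi(self, rng):
        n = 2000
        x = rng.integers(0, 20, n)
        y = rng.integers(0, 20, n)
        plain = decompose(x, y, 20)
        corrected = decompose(x, y, 20, miller_madow=True)
        assert corrected.mi < plain.mi

    @given(
        st.lists(
            st.tuples(st.integers(0, 9), st.integers(0, 9)), min_size=1, max_size=200
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_information_inequalities(self, pairs):
        """H >= 0, I >= 0, I <= min(H), chain identity — on arbitrary pairs."""
        x = [p[0] for p in pairs]
        y = [p[1] for p in pairs]
        d = decompose(x, y, 10)
        assert d.h_x >= 0 and d.h_y >= 0 and d.mi >= 0
        assert d.h_x <= math.log2(10) + 1e-9
        assert d.mi <= min(d.h_x, d.h_y) + 1e-9
        assert d.h_x_given_y + d.mi == pytest.approx(d.h_x, abs=1e-9)
        assert d.h_y_given_x + d.mi == pytest.approx(d.h_y, abs=1e-9)


def test_gaussian_closed_form_limit(rng):
    """Binned plug-in MI approaches -0.5*log2(1-rho^2) for Gaussian pairs."""
    n = 100_000
    for rho in (0.3, 0.6, 0.9):
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + math.sqrt(1 - rho**2) * rng.standard_normal(n)
        bx = np.floor((z1 - z1.min()) / ((z1.max() - z1.min()) / 20)).clip(0, 19).astype(int)
        by = np.floor((z2 - z2.min()) / ((z2.max() - z2.min()) / 20)).clip(0, 19).astype(int)
        estimate = decompose(bx, by, 20).mi
        truth = -0.5 * math.log2(1 - rho**2)
        assert abs(estimate - truth) < 0.1, (rho, estimate, truth)
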