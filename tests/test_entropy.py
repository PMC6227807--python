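import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from entroscape.entropy import (
    BinaryDistribution,
    JointBinaryDistribution,
    bernoulli_variance,
    binary_entropy,
    entropy_james_stein,
    entropy_miller_madow,
    entropy_ml,
    fit_binary_distribution,
    fit_joint_distribution,
    joint_entropy,
    mutual_information,
    normalize_entropy,
)
from entroscape.exceptions import InputError

H_QUARTER = 0.8112781244591328  # -0.25 log2 0.25 - 0.75 log2 0.75


def brute_entropy_bits(counts):
    """Independent plug-in entropy via rational probabilities."""
    n = sum(counts)
    h = 0.0
    for c in counts:
        if c:
            p = Fraction(c, n)
            h -= float(p) * math.log2(float(p))
    return h


probs = st.floats(min_value=0.0, max_value=1.0)


@st.composite
def joint_distributions(draw):
    raw = [draw(st.floats(min_value=0.0, max_value=1.0)) for _ in range(4)]
    total = sum(raw)
    if total == 0:
        raw = [1.0, 0.0, 0.0, 0.0]
        total = 1.0
    p = [r / total for r in raw]
    p[3] = 1.0 - p[0] - p[1] - p[2]
    return JointBinaryDistribution(p00=p[0], p01=p[1], p10=p[2], p11=max(p[3], 0.0))


class TestFitDistributions:
    def test_symmetric_counts(self):
        d = fit_binary_distribution([1, 1, 0, 0])
        assert d.p1 == 0.5 and d.n == 4

    def test_degenerate_all_off(self):
        d = fit_binary_distribution([0, 0, 0])
        assert d.p1 == 0.0 and d.n == 3

    def test_count_ratio(self):
        assert fit_binary_distribution([1, 0, 0, 0]).p1 == 0.25

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            fit_binary_distribution([])

    def test_non_binary_rejected(self):
        with pytest.raises(InputError):
            fit_binary_distribution([0, 2, 1])

    def test_joint_fit_state_order(self):
        j = fit_joint_distribution([1, 1, 0, 0], [1, 0, 1, 0])
        assert (j.p00, j.p01, j.p10, j.p11) == (0.25, 0.25, 0.25, 0.25)
        assert j.n == 4


class TestBinaryEntropy:
    def test_maximum_at_half(self):
        assert binary_entropy(BinaryDistribution(0.5, 0.5)) == 1.0

    @pytest.mark.parametrize("p1", [0.0, 1.0])
    def test_zero_at_degenerate(self, p1):
        assert binary_entropy(BinaryDistribution(1 - p1, p1)) == 0.0

    def test_quarter(self):
        assert binary_entropy(BinaryDistribution(0.75, 0.25)) == pytest.approx(
            H_QUARTER, abs=1e-12
        )

    @given(probs)
    def test_symmetric_in_p(self, p):
        a = binary_entropy(BinaryDistribution(1 - p, p))
        b = binary_entropy(BinaryDistribution(p, 1 - p))
        assert a == pytest.approx(b, abs=1e-12)
        assert 0.0 <= a <= 1.0 + 1e-12

    @given(st.floats(min_value=0.0, max_value=0.499))
    def test_strictly_increasing_below_half(self, p):
        lo = binary_entropy(BinaryDistribution(1 - p, p))
        hi = binary_entropy(BinaryDistribution(1 - p - 1e-6, p + 1e-6))
        assert hi > lo

    def test_invalid_distribution(self):
        with pytest.raises(InputError):
            BinaryDistribution(0.6, 0.6)


class TestJointEntropy:
    def test_uniform_is_two_bits(self):
        assert joint_entropy(
            JointBinaryDistribution(0.25, 0.25, 0.25, 0.25)
        ) == 2.0

    def test_two_equiprobable_states(self):
        assert joint_entropy(JointBinaryDistribution(0.5, 0.0, 0.0, 0.5)) == 1.0

    def test_point_mass(self):
        assert joint_entropy(JointBinaryDistribution(1.0, 0.0, 0.0, 0.0)) == 0.0

    @given(joint_distributions())
    def test_product_rule(self, j):
        a, b = j.marginals()
        prod = JointBinaryDistribution(
            p00=a.p0 * b.p0, p01=a.p0 * b.p1, p10=a.p1 * b.p0, p11=a.p1 * b.p1
        )
        expected = binary_entropy(a) + binary_entropy(b)
        assert joint_entropy(prod) == pytest.approx(expected, abs=1e-9)
        assert mutual_information(prod) == pytest.approx(0.0, abs=1e-9)


class TestNormalizeEntropy:
    def test_maximal_joint(self):
        assert normalize_entropy(2.0, 4) == 1.0

    def test_half(self):
        assert normalize_entropy(1.0, 4) == 0.5

    def test_binary_passthrough(self):
        assert normalize_entropy(0.7, 2) == 0.7

    def test_excess_rejected(self):
        with pytest.raises(InputError):
            normalize_entropy(1.2, 2)

    def test_excess_allowed_when_flagged(self):
        # Miller-Madow output path: keep the excess visible
        assert normalize_entropy(1.2, 2, allow_excess=True) == 1.2


class TestMutualInformation:
    def test_independent_fair_coins(self):
        assert mutual_information(
            JointBinaryDistribution(0.25, 0.25, 0.25, 0.25)
        ) == pytest.approx(0.0, abs=1e-12)

    def test_perfectly_correlated(self):
        assert mutual_information(
            JointBinaryDistribution(0.5, 0.0, 0.0, 0.5)
        ) == pytest.approx(1.0, abs=1e-12)

    @given(joint_distributions())
    def test_non_negative(self, j):
        assert mutual_information(j) >= 0.0

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=200)
    def test_half_mi_identity_for_symmetric_marginals(self, u, v):
        # symmetric marginals: p01 == p10
        p11 = u * v
        p01 = p10 = (1 - u) * v / 2
        p00 = 1 - p11 - p01 - p10
        j = JointBinaryDistribution(p00=p00, p01=p01, p10=p10, p11=p11)
        a, _ = j.marginals()
        gap = binary_entropy(a) - joint_entropy(j) / 2.0
        assert gap == pytest.approx(mutual_information(j) / 2.0, abs=1e-12)


class TestBernoulliVariance:
    @pytest.mark.parametrize(
        "p1,expected", [(0.5, 0.25), (0.0, 0.0), (1.0, 0.0), (0.25, 0.1875)]
    )
    def test_values(self, p1, expected):
        assert bernoulli_variance(BinaryDistribution(1 - p1, p1)) == expected

    def test_co_monotone_with_entropy_below_half(self):
        ps = np.linspace(0.0, 0.5, 101)
        hs = [binary_entropy(BinaryDistribution(1 - p, p)) for p in ps]
        vs = [bernoulli_variance(BinaryDistribution(1 - p, p)) for p in ps]
        assert all(np.diff(hs) > 0) and all(np.diff(vs) > 0)


class TestEstimators:
    def test_ml_matches_rational_brute_force_four_states(self):
        for n in range(1, 9):
            for counts in itertools.product(range(n + 1), repeat=4):
                if sum(counts) != n:
                    continue
                assert entropy_ml(list(counts)) == pytest.approx(
                    brute_entropy_bits(counts), abs=1e-12
                )

    def test_miller_madow_frozen_values(self):
        assert entropy_miller_madow([3, 1]) == pytest.approx(
            0.9916150045702532, abs=1e-12
        )
        assert entropy_miller_madow([4, 0]) == 0.0
        # overcorrection: exceeds the 1-bit ceiling
        assert entropy_miller_madow([2, 2]) == pytest.approx(
            1.1803368801111205, abs=1e-12
        )
        assert entropy_miller_madow([2, 2]) > 1.0

    def test_miller_madow_dominates_ml(self):
        for n in range(1, 9):
            for k in range(n + 1):
                ml = entropy_ml([n - k, k])
                mm = entropy_miller_madow([n - k, k])
                if k in (0, n):  # single occupied state: zero correction
                    assert mm == ml
                else:
                    assert mm > ml

    def test_james_stein_fixed_points(self):
        assert entropy_james_stein([50, 50]) == 1.0
        assert entropy_james_stein([1, 1]) == 1.0

    def test_james_stein_full_shrinkage_at_tiny_n(self):
        # lambda = (1 - 0.625) / (3 * 0.125) = 1 exactly, so the shrunk
        # distribution is uniform and the estimate hits the 1-bit ceiling
        assert entropy_james_stein([3, 1]) == 1.0

    def test_james_stein_between_ml_and_uniform(self):
        # counts (30, 10): lambda = 0.375 / (39 * 0.125) = 1/13
        h = entropy_james_stein([30, 10])
        assert entropy_ml([30, 10]) < h < 1.0
        assert h == pytest.approx(0.8403586716091171, abs=1e-12)

    def test_james_stein_needs_two_observations(self):
        with pytest.raises(InputError):
            entropy_james_stein([1, 0])

    def test_estimators_reject_bad_counts(self):
        with pytest.raises(InputError):
            entropy_ml([0, 0])
        with pytest.raises(InputError):
            entropy_miller_madow([-1, 2])

    def test_vectorized_counts(self):
        counts = np.array([[3, 1], [2, 2], [4, 0]])
        out = entropy_ml(counts)
        assert out.shape == (3,)
        assert out[0] == pytest.approx(H_QUARTER, abs=1e-12)

    @given(st.integers(1, 30), st.integers(0, 30))
    def test_ml_within_one_bit(self, a, b):
        h = entropy_ml([a, b])
        assert 0.0 <= h <= 1.0 + 1e-12
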