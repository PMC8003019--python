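"""Closed-form birth-death probabilities: examples and invariants."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dtcfate import (
    BranchingParams,
    extinction_prob_at_time,
    lineage_extinction_prob,
    p_tumor,
    p_tumor_curve,
)

RATIOS = st.floats(min_value=0.0, max_value=2.0, allow_nan=False)
FRACTIONS = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)
COUNTS = st.integers(min_value=0, max_value=200)


class TestBranchingParams:
    @pytest.mark.parametrize(
        "birth,death", [(-1.0, 1.0), (1.0, -0.5), (0.0, 0.0)]
    )
    def test_invalid_rates_rejected(self, birth, death):
        with pytest.raises(ValueError):
            BranchingParams(birth, death)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            BranchingParams(1.0, 0.5, proliferative_fraction=1.5)

    def test_ratio_infinite_without_births(self):
        assert BranchingParams(0.0, 1.0).ratio == math.inf


class TestLineageExtinction:
    @pytest.mark.parametrize(
        "birth,death,expected",
        [
            (1.0, 2.0, 1.0),     # subcritical: extinction certain
            (1.0, 0.0, 0.0),     # no deaths: lineage immortal
            (1.0, 0.885, 0.885), # supercritical: q equals the rate ratio
            (0.0, 1.0, 1.0),     # pure death
            (2.0, 1.77, 0.885),  # depends only on the ratio
        ],
    )
    def test_extinction_probability(self, birth, death, expected):
        q = lineage_extinction_prob(BranchingParams(birth, death))
        assert q == pytest.approx(expected)


class TestExtinctionAtTime:
    def test_zero_time_means_alive(self):
        assert extinction_prob_at_time(0.0, BranchingParams(1.0, 0.885)) == 0.0

    def test_critical_case(self):
        # lam = mu = 1, t = 1 -> lam t / (1 + lam t) = 1/2
        assert extinction_prob_at_time(1.0, BranchingParams(1.0, 1.0)) == pytest.approx(0.5)

    def test_long_time_limit_matches_lineage_extinction(self):
        params = BranchingParams(1.0, 0.885)
        assert extinction_prob_at_time(200.0, params) == pytest.approx(0.885, abs=1e-6)

    def test_pure_death_is_exponential_cdf(self):
        params = BranchingParams(0.0, 0.5)
        assert extinction_prob_at_time(3.0, params) == pytest.approx(1 - math.exp(-1.5))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            extinction_prob_at_time(-1.0, BranchingParams(1.0, 1.0))

    @given(
        mu=st.floats(min_value=0.1, max_value=3.0),
        times=st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=2, max_size=8),
    )
    def test_monotone_in_time_and_bounded_by_limit(self, mu, times):
        params = BranchingParams(1.0, mu)
        qs = [extinction_prob_at_time(t, params) for t in sorted(times)]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
        assert all(0.0 <= q <= lineage_extinction_prob(params) + 1e-12 for q in qs)


class TestPTumor:
    def test_no_cells_no_tumor(self):
        assert p_tumor(0, BranchingParams.from_ratio(0.1)) == 0.0

    def test_single_cell_is_escape_probability(self):
        assert p_tumor(1, BranchingParams.from_ratio(0.885)) == pytest.approx(0.115)

    def test_ten_cells_all_proliferative(self):
        # direct arithmetic oracle: 1 - 0.885**10
        expected = 1.0 - 0.885**10
        assert p_tumor(10, BranchingParams.from_ratio(0.885)) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.7053, abs=1e-4)

    def test_ten_cells_restricted_proliferation(self):
        # mixture oracle: 1 - (1 - 0.11 * 0.115)**10
        expected = 1.0 - (1.0 - 0.11 * 0.115) ** 10
        got = p_tumor(10, BranchingParams.from_ratio(0.885, 0.11))
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.1195, abs=1e-4)

    @pytest.mark.parametrize("bad_n", [-1, 1.5, -3.0])
    def test_invalid_counts_rejected(self, bad_n):
        with pytest.raises((ValueError, TypeError)):
            p_tumor(bad_n, BranchingParams.from_ratio(0.5))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            p_tumor(1, BranchingParams.from_ratio(0.5), variant="weird")

    @given(ratio=st.floats(min_value=1.0, max_value=5.0), n=COUNTS, f=FRACTIONS)
    def test_at_or_above_criticality_no_outgrowth(self, ratio, n, f):
        params = BranchingParams.from_ratio(ratio, f)
        assert p_tumor(n, params) == 0.0
        assert p_tumor(n, params, variant="exponent") == 0.0

    @given(ratio=st.floats(min_value=0.0, max_value=0.999), n=COUNTS)
    def test_fully_proliferative_reduces_to_power_form(self, ratio, n):
        params = BranchingParams.from_ratio(ratio, 1.0)
        assert p_tumor(n, params) == 1.0 - ratio**n

    @given(ratio=RATIOS, f=FRACTIONS, n=st.integers(min_value=0, max_value=100))
    def test_monotone_in_founder_count(self, ratio, f, n):
        params = BranchingParams.from_ratio(ratio, f)
        assert p_tumor(n + 1, params) >= p_tumor(n, params) - 1e-15

    @given(
        a=st.floats(min_value=0.0, max_value=2.0),
        b=st.floats(min_value=0.0, max_value=2.0),
        n=st.integers(min_value=1, max_value=50),
        f=FRACTIONS,
    )
    def test_monotone_nonincreasing_in_ratio(self, a, b, n, f):
        lo, hi = sorted((a, b))
        p_lo = p_tumor(n, BranchingParams.from_ratio(lo, f))
        p_hi = p_tumor(n, BranchingParams.from_ratio(hi, f))
        assert p_lo >= p_hi - 1e-12

    @given(
        ratio=st.floats(min_value=0.01, max_value=1.5),
        c=st.floats(min_value=0.01, max_value=100.0),
        n=st.integers(min_value=0, max_value=50),
        f=FRACTIONS,
    )
    def test_time_rescaling_invariance(self, ratio, c, n, f):
        base = BranchingParams(1.0, ratio, f)
        scaled = BranchingParams(c, c * ratio, f)
        assert p_tumor(n, base) == pytest.approx(p_tumor(n, scaled), abs=1e-12)

    def test_limit_is_certain_outgrowth(self):
        params = BranchingParams.from_ratio(0.885, 0.11)
        assert p_tumor(5000, params) == pytest.approx(1.0, abs=1e-12)


class TestPTumorCurve:
    def test_known_pairs(self):
        pairs = p_tumor_curve([0, 1], BranchingParams.from_ratio(0.885))
        assert pairs[0] == (0, 0.0)
        assert pairs[1][0] == 1
        assert pairs[1][1] == pytest.approx(0.115)

    def test_empty_input(self):
        assert p_tumor_curve([], BranchingParams.from_ratio(0.5)) == []

    def test_repeated_counts_give_identical_pairs(self):
        pairs = p_tumor_curve([5, 5], BranchingParams.from_ratio(0.7))
        assert pairs[0] == pairs[1]
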