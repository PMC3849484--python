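"""Bland-Altman agreement and cumulative-difference curves."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ihcquant.agreement import (
    bland_altman,
    difference_curve,
    paired_counts,
    stratified_compare,
)


def pairs_of(a, b, stratum=None):
    ids = [f"im{i}" for i in range(len(a))]
    return paired_counts(ids, a, b, stratum)


class TestBlandAltman:
    def test_identical_pairs_zero_spread(self):
        s = bland_altman(pairs_of([10, 25, 90], [10, 25, 90]))
        assert s.mean_diff == 0 and s.sd_diff == 0
        assert (s.loa_low, s.loa_high) == (0, 0)

    def test_worked_three_pair_example(self):
        """diffs {-2, 2, -3}: mean -1, sample sd sqrt(7), LoA -1 +- 1.96 sqrt(7)."""
        s = bland_altman(pairs_of([10, 20, 30], [12, 18, 33]))
        assert s.n == 3
        assert s.mean_diff == pytest.approx(-1.0, abs=1e-12)
        assert s.sd_diff == pytest.approx(math.sqrt(7), abs=1e-12)
        assert s.loa_low == pytest.approx(-1 - 1.96 * math.sqrt(7), abs=1e-12)
        assert s.loa_high == pytest.approx(-1 + 1.96 * math.sqrt(7), abs=1e-12)
        assert s.points[0] == (11.0, -2.0)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(pairs_of([10], [12]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(0, 500)),
            min_size=2,
            max_size=30,
        )
    )
    def test_antisymmetric_under_swap(self, raw):
        a = [p[0] for p in raw]
        b = [p[1] for p in raw]
        s_ab = bland_altman(pairs_of(a, b))
        s_ba = bland_altman(pairs_of(b, a))
        assert s_ba.mean_diff == pytest.approx(-s_ab.mean_diff)
        assert s_ba.sd_diff == pytest.approx(s_ab.sd_diff)
        assert s_ba.loa_low == pytest.approx(-s_ab.loa_high)
        assert s_ba.loa_high == pytest.approx(-s_ab.loa_low)
        assert s_ab.loa_low <= s_ab.mean_diff <= s_ab.loa_high


class TestDifferenceCurve:
    def test_counting_example(self):
        """|diffs| {0, 10, 50, 60}: P(>=50) = 2/4."""
        c = difference_curve(pairs_of([100, 110, 150, 160], [100, 100, 100, 100]))
        assert c.probability_at(50) == 0.5
        assert c.probability_at(0) == 1.0
        assert c.probability_at(61) == 0.0

    def test_all_zero_diffs(self):
        c = difference_curve(pairs_of([5, 6, 7], [5, 6, 7]))
        assert c.probability_at(0) == 1.0
        for d in (0.5, 1, 10):
            assert c.probability_at(d) == 0.0

    def test_single_pair(self):
        c = difference_curve(pairs_of([10], [17]))
        assert c.probability_at(7) == 1.0
        assert c.probability_at(8) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            difference_curve(pairs_of([], []))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 300), st.integers(0, 300)),
            min_size=1,
            max_size=40,
        )
    )
    def test_survival_curve_shape(self, raw):
        """Starts at 1, non-increasing, bounded in [0, 1], 0 past the max."""
        c = difference_curve(pairs_of([p[0] for p in raw], [p[1] for p in raw]))
        assert c.thresholds[0] == 0.0 and c.probabilities[0] == 1.0
        assert all(
            p1 >= p2 for p1, p2 in zip(c.probabilities, c.probabilities[1:])
        )
        assert all(0.0 <= p <= 1.0 for p in c.probabilities)
        assert c.probability_at(c.thresholds[-1] + 1) == 0.0


class TestStratified:
    def test_identical_strata_identical_summaries(self):
        pairs = pairs_of([10, 20, 10, 20], [12, 18, 12, 18],
                         stratum=["A", "A", "B", "B"])
        out = stratified_compare(pairs)
        sa, sb = out["A"][0], out["B"][0]
        assert sa.mean_diff == sb.mean_diff and sa.sd_diff == sb.sd_diff

    def test_pooled_n_equals_sum_of_strata(self):
        rng = np.random.default_rng(0)
        n = 25
        pairs = pairs_of(
            rng.integers(0, 200, n), rng.integers(0, 200, n),
            stratum=list(rng.choice(["LOW", "HIGH"], n)),
        )
        out = stratified_compare(pairs)
        assert sum(s.n if s else 1 for s, _ in out.values()) == n

    def test_stratum_curve_equals_subset_curve(self):
        rng = np.random.default_rng(1)
        n = 30
        strata = list(rng.choice(["X", "Y"], n))
        pairs = pairs_of(rng.integers(0, 200, n), rng.integers(0, 200, n), strata)
        out = stratified_compare(pairs)
        for key in ("X", "Y"):
            sub = pairs[pairs["stratum"] == key]
            expected = difference_curve(sub)
            assert out[key][1] == expected

    def test_singleton_stratum_has_curve_only(self):
        pairs = pairs_of([10, 20, 30], [12, 18, 35], stratum=["A", "A", "B"])
        out = stratified_compare(pairs)
        assert out["B"][0] is None
        assert out["B"][1].probability_at(5) == 1.0

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            stratified_compare(pairs_of([1, 2], [1, 2]), by="missing")
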