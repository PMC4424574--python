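import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from plexdose.stats import (ContingencyTable2x2, ddct_copy_number,
                            fisher_exact, group_frequency_table,
                            sensitivity_specificity)


def fisher_two_sided_oracle(a, b, c, d):
    """Exact-arithmetic enumeration of all 2x2 tables with the observed
    margins; sums point probabilities at most (1 + 1e-7) times the observed
    one.  Independent of the summation routine under test."""
    row1, row2 = a + b, c + d
    col1 = a + c
    total = row1 + row2
    denom = math.comb(total, col1)
    pmf = {}
    for k in range(max(0, col1 - row2), min(row1, col1) + 1):
        pmf[k] = Fraction(math.comb(row1, k) * math.comb(row2, col1 - k), denom)
    cutoff = pmf[a] * (Fraction(10 ** 7 + 1, 10 ** 7))
    return float(sum(p for p in pmf.values() if p <= cutoff))


class TestFisherExact:
    def test_degenerate_margin_single_table(self):
        assert fisher_exact([[0, 10], [0, 10]]) == 1.0

    def test_small_table_matches_enumeration(self):
        table = [[3, 7], [1, 9]]
        assert fisher_exact(table) == pytest.approx(
            fisher_two_sided_oracle(3, 7, 1, 9), rel=1e-9)

    @settings(max_examples=200, derandomize=True)
    @given(st.tuples(st.integers(0, 60), st.integers(0, 60),
                     st.integers(0, 60), st.integers(0, 60))
           .filter(lambda t: 0 < sum(t) <= 200))
    def test_matches_enumeration_oracle_up_to_n200(self, counts):
        a, b, c, d = counts
        assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
            fisher_two_sided_oracle(a, b, c, d), rel=1e-9, abs=0)

    @settings(max_examples=50, derandomize=True)
    @given(st.tuples(st.integers(0, 40), st.integers(0, 40),
                     st.integers(0, 40), st.integers(0, 40))
           .filter(lambda t: sum(t) > 0))
    def test_invariant_to_simultaneous_row_and_column_swap(self, counts):
        a, b, c, d = counts
        p1 = fisher_exact([[a, b], [c, d]])
        p2 = fisher_exact([[d, c], [b, a]])
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_agrees_with_scipy_on_cohort_tables(self):
        for table in ([[38, 577], [1, 202]], [[9, 809], [2, 6531]],
                      [[11, 807], [3, 6530]], [[5, 5], [5, 5]]):
            assert fisher_exact(table) == pytest.approx(
                sps.fisher_exact(table)[1], rel=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(1, 20), st.integers(1, 20), st.integers(0, 20),
           st.integers(0, 20))
    def test_one_sided_greater_monotone_in_a(self, a, b, c, d):
        # moving one count from b to a and from c to d (margins fixed)
        # makes the upper tail smaller or equal
        p_lo = fisher_exact([[a - 1, b], [c + 1, d]], sided="greater")
        p_hi = fisher_exact([[a, b - 1], [c, d + 1]], sided="greater")
        assert p_hi <= p_lo + 1e-12

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestGroupFrequencyTable:
    def test_cohort_percentages(self):
        carriers, groups = {}, {}
        for group, n, k in (("CTD", 615, 38), ("non-CTD", 203, 1),
                            ("PA/VSD", 135, 17)):
            for i in range(n):
                sid = f"{group}-{i}"
                carriers[sid] = i < k
                groups[sid] = group
        table = group_frequency_table(carriers, groups).set_index("group")
        assert table.loc["CTD", "percent"] == 6.2
        assert table.loc["non-CTD", "percent"] == 0.5
        assert table.loc["PA/VSD", "percent"] == 12.6

    def test_zero_carriers_zero_percent(self):
        table = group_frequency_table({"a": False, "b": False},
                                      {"a": "g", "b": "g"})
        assert table["percent"].iloc[0] == 0.0
        assert table["carriers"].iloc[0] == 0

    def test_labels_accepted_in_place_of_flags(self):
        table = group_frequency_table({"a": "A-D", "b": "normal"},
                                      {"a": "g", "b": "g"})
        assert table["carriers"].iloc[0] == 1


class TestDdct:
    def test_identity_is_diploid(self):
        result = ddct_copy_number(25, 25, 25, 25)
        assert result.copy_number == 2.0
        assert result.classification == "normal"

    def test_one_extra_cycle_is_het_deletion(self):
        # ddCT = +1 halves the relative quantity: N = 1, a 50% decrease
        result = ddct_copy_number(26.0, 25.0, 25.0, 25.0)
        assert result.ddct == 1.0
        assert result.copy_number == 1.0
        assert result.classification == "deletion"

    def test_three_copies_is_duplication(self):
        result = ddct_copy_number(25.0 - math.log2(1.5), 25.0, 25.0, 25.0)
        assert result.copy_number == pytest.approx(3.0)
        assert result.classification == "duplication"

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=-3, max_value=3,
                     allow_nan=False, allow_infinity=False))
    def test_round_trip_copy_number_to_ddct(self, ddct):
        result = ddct_copy_number(25 + ddct, 25, 25, 25)
        back = -math.log2(result.copy_number / 2.0)
        assert back == pytest.approx(ddct, abs=1e-9)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(ValueError):
            ddct_copy_number(float("nan"), 25, 25, 25)


class TestSensitivitySpecificity:
    def test_perfect_agreement(self):
        truth = {f"s{i}": i < 9 for i in range(110)}
        assert sensitivity_specificity(truth, truth) == (100.0, 100.0)

    def test_all_normal_predictions_miss_carriers(self):
        truth = {"a": True, "b": False}
        pred = {"a": False, "b": False}
        sens, spec = sensitivity_specificity(pred, truth)
        assert sens == 0.0 and spec == 100.0

    def test_one_false_positive_among_101_normals(self):
        truth = {f"s{i}": i < 9 for i in range(110)}
        pred = dict(truth)
        pred["s9"] = True
        sens, spec = sensitivity_specificity(pred, truth)
        assert sens == 100.0
        assert spec == pytest.approx(100 * 100 / 101)

    def test_mismatched_sample_sets_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            sensitivity_specificity({"a": True}, {"b": True})
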