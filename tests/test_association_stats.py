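import math

import numpy as np
import pytest
from scipy import stats as sps

from rarecnv.association_stats import (
    SizeBins,
    association_summary,
    bin_by_size,
    odds_ratio_woolf,
    summary_to_frame,
    two_proportion_test,
)
from rarecnv.errors import ConfigurationError
from rarecnv.models import CnvType, CohortRecord, CohortTable, Phenotype

from conftest import make_call


class TestSizeBins:
    def test_exact_edge_goes_up(self):
        bins = SizeBins()
        call = make_call(start=1, end=100_000)  # exactly 100 kb
        assert bin_by_size([call], bins)["100KB_200KB"] == [call]

    def test_large_call_last_bin(self):
        call = make_call(start=1, end=1_500_000)
        assert bin_by_size([call])["1000KB_1000000KB"] == [call]

    def test_just_above_lowest_edge(self):
        call = make_call(start=1, end=50_001)
        assert bin_by_size([call])["50KB_100KB"] == [call]

    def test_below_lowest_edge_errors(self):
        with pytest.raises(ConfigurationError, match="size filter"):
            bin_by_size([make_call(start=1, end=10_000)])

    def test_every_call_in_exactly_one_bin(self):
        rng = np.random.default_rng(0)
        calls = [make_call(start=1, end=int(e))
                 for e in rng.integers(50_000, 3_000_000, 100)]
        binned = bin_by_size(calls)
        assert sum(len(v) for v in binned.values()) == len(calls)

    def test_non_increasing_edges_rejected(self):
        with pytest.raises(ConfigurationError):
            SizeBins((50.0, 50.0, 100.0))


class TestTwoProportionTest:
    def test_equal_proportions_give_p_one(self):
        assert two_proportion_test(10, 100, 30, 300) == pytest.approx(1.0)

    def test_agrees_with_chi2_contingency_oracle(self):
        # independent oracle: scipy's contingency-table implementation
        rng = np.random.default_rng(7)
        for _ in range(300):
            n1, n2 = int(rng.integers(5, 500)), int(rng.integers(5, 500))
            a, b = int(rng.integers(1, n1)), int(rng.integers(1, n2))
            table = np.array([[a, n1 - a], [b, n2 - b]])
            if (table == 0).any():
                continue
            expected = sps.chi2_contingency(table, correction=False)[1]
            assert two_proportion_test(a, n1, b, n2, correction=False) == pytest.approx(
                expected, abs=1e-10)

    def test_empty_cohort_errors(self):
        with pytest.raises(ConfigurationError):
            two_proportion_test(0, 0, 1, 10)


class TestOddsRatioWoolf:
    def test_symmetric_table(self):
        or_est, lo, hi, _ = odds_ratio_woolf(50, 100, 50, 100)
        assert or_est == pytest.approx(1.0)
        assert math.log(lo) == pytest.approx(-math.log(hi))

    def test_inversion_symmetry(self):
        or1 = odds_ratio_woolf(30, 120, 70, 300)[0]
        or2 = odds_ratio_woolf(70, 300, 30, 120)[0]
        assert or1 == pytest.approx(1 / or2)

    def test_doubling_cohorts_shrinks_ci(self):
        _, lo1, hi1, _ = odds_ratio_woolf(30, 120, 70, 300)
        or2, lo2, hi2, _ = odds_ratio_woolf(60, 240, 140, 600)
        assert or2 == pytest.approx(odds_ratio_woolf(30, 120, 70, 300)[0])
        assert hi2 - lo2 < hi1 - lo1

    def test_agrees_with_independent_oracle(self):
        # oracle: statsmodels' Table2x2 log-OR confint (same Woolf model,
        # independent implementation)
        sm_ct = pytest.importorskip("statsmodels.stats.contingency_tables")
        rng = np.random.default_rng(13)
        for _ in range(200):
            n1, n2 = int(rng.integers(10, 400)), int(rng.integers(10, 400))
            a, b = int(rng.integers(1, n1)), int(rng.integers(1, n2))
            t = sm_ct.Table2x2(np.array([[a, n1 - a], [b, n2 - b]]))
            or_est, lo, hi, _ = odds_ratio_woolf(a, n1, b, n2)
            assert or_est == pytest.approx(t.oddsratio, abs=1e-10)
            exp_lo, exp_hi = t.oddsratio_confint(0.05)
            assert lo == pytest.approx(exp_lo, rel=1e-9)
            assert hi == pytest.approx(exp_hi, rel=1e-9)

    def test_zero_cell_haldane(self):
        or_est, lo, hi, p = odds_ratio_woolf(0, 50, 5, 100)
        assert 0 < or_est < 1
        assert 0 < lo < or_est < hi

    def test_degenerate_margins_error(self):
        with pytest.raises(ConfigurationError):
            odds_ratio_woolf(10, 10, 20, 20)


class TestAssociationSummary:
    def _cohort(self, n1=50, n2=100):
        recs = [CohortRecord(f"A{i}", Phenotype.CASE) for i in range(n1)]
        recs += [CohortRecord(f"B{i}", Phenotype.CONTROL) for i in range(n2)]
        return CohortTable(recs)

    def _calls(self):
        calls = []
        for i in range(10):  # 10 case DELs at 60 kb
            calls.append(make_call(sample=f"A{i % 50}", start=1, end=60_000, cn=1))
        for i in range(12):  # 12 control DELs at 250 kb
            calls.append(make_call(sample=f"B{i}", start=1, end=250_000, cn=1))
        for i in range(4):   # 4 case DUPs at 1.2 Mb
            calls.append(make_call(sample=f"A{i}", start=1, end=1_200_000, cn=3))
        return calls

    def test_all_row_equals_bin_sum(self):
        results = association_summary(self._calls(), self._cohort())
        for cnv_type in CnvType:
            rows = [r for r in results if r.cnv_type is cnv_type]
            all_row = next(r for r in rows if r.bin_label == "ALL")
            assert all_row.a == sum(r.a for r in rows if r.bin_label != "ALL")
            assert all_row.b == sum(r.b for r in rows if r.bin_label != "ALL")

    def test_counts_and_frequencies(self):
        results = association_summary(self._calls(), self._cohort())
        by = {(r.cnv_type.value, r.bin_label): r for r in results}
        r = by[("DEL", "ALL")]
        assert (r.a, r.b) == (10, 12)
        assert r.case_freq == pytest.approx(10 / 50)
        assert r.control_freq == pytest.approx(12 / 100)
        assert by[("DEL", "50KB_100KB")].a == 10
        assert by[("DUP", "1000KB_1000000KB")].a == 4

    def test_empty_bin_flagged_undefined(self):
        results = association_summary(self._calls(), self._cohort())
        by = {(r.cnv_type.value, r.bin_label): r for r in results}
        empty = by[("DUP", "500KB_1000KB")]
        assert (empty.a, empty.b) == (0, 0)
        assert empty.or_estimate is None and empty.p_two_prop is None

    def test_label_swap_inverts_or(self):
        cohort = self._cohort()
        swapped = CohortTable(
            CohortRecord(r.sample_id,
                         Phenotype.CONTROL if r.phenotype is Phenotype.CASE
                         else Phenotype.CASE)
            for r in cohort)
        res1 = {(r.cnv_type.value, r.bin_label): r
                for r in association_summary(self._calls(), cohort)}
        res2 = {(r.cnv_type.value, r.bin_label): r
                for r in association_summary(self._calls(), swapped)}
        for key, r1 in res1.items():
            if r1.or_estimate is None or res2[key].or_estimate is None:
                continue
            assert r1.or_estimate == pytest.approx(1 / res2[key].or_estimate)

    def test_summary_frame_columns(self):
        frame = summary_to_frame(association_summary(self._calls(), self._cohort()))
        assert list(frame.columns) == [
            "CNV", "Length", "Cases", "Controls", "Cases_freq", "Controls_freq",
            "P.value", "OR", "X95.CI", "P",
        ]

    def test_requires_both_groups(self):
        cohort = CohortTable([CohortRecord("A", Phenotype.CASE)])
        with pytest.raises(ConfigurationError):
            association_summary([], cohort)
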