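import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rarecnv.errors import ConfigurationError
from rarecnv.models import CnvType, CohortRecord, CohortTable, Phenotype
from rarecnv.rare_extraction import (
    CommonCnv,
    RareConfig,
    carrier_frequency_table,
    filter_rare,
    identify_common,
    overlap_counts,
    query_fraction,
    select_reference_controls,
    union_overlap_fraction,
)

from conftest import make_call


class TestUnionOverlapFraction:
    def test_identical(self):
        a = make_call(start=10, end=100)
        assert union_overlap_fraction(a, a) == 1.0

    def test_disjoint(self):
        a = make_call(start=1, end=100)
        b = make_call(start=200, end=300)
        assert union_overlap_fraction(a, b) == 0.0

    def test_forced_arithmetic(self):
        # 1-100 vs 51-150: intersection 50, union 150
        a = make_call(start=1, end=100)
        b = make_call(start=51, end=150)
        assert union_overlap_fraction(a, b) == pytest.approx(1 / 3)

    def test_different_chrom(self):
        a = make_call(start=1, end=100, chrom="1")
        b = make_call(start=1, end=100, chrom="2")
        assert union_overlap_fraction(a, b) == 0.0

    @given(
        s1=st.integers(1, 1000), l1=st.integers(1, 500),
        s2=st.integers(1, 1000), l2=st.integers(1, 500),
    )
    def test_symmetric_and_bounded(self, s1, l1, s2, l2):
        a = make_call(start=s1, end=s1 + l1)
        b = make_call(start=s2, end=s2 + l2)
        f = union_overlap_fraction(a, b)
        assert f == union_overlap_fraction(b, a)
        assert 0.0 <= f <= 1.0

    def test_monotone_under_intersection_growth(self):
        a = make_call(start=1, end=100)
        fracs = [union_overlap_fraction(a, make_call(start=s, end=s + 99))
                 for s in (90, 60, 30, 1)]
        assert fracs == sorted(fracs)


def brute_force_counts(calls, threshold):
    """O(n^2) all-pairs oracle, straight from the definition."""
    out = []
    for a in calls:
        out.append(sum(
            1 for b in calls if union_overlap_fraction(a, b) >= threshold))
    return out


class TestOverlapCounts:
    def test_lone_cnv_counts_itself(self):
        assert overlap_counts([make_call()]) == [1]

    def test_two_identical_in_different_samples(self):
        calls = [make_call(sample="A"), make_call(sample="B")]
        assert overlap_counts(calls) == [2, 2]

    def test_mixed_types_rejected(self):
        calls = [make_call(cn=1), make_call(cn=3)]
        with pytest.raises(ConfigurationError):
            overlap_counts(calls)

    @settings(max_examples=60, deadline=None)
    @given(
        n=st.integers(0, 40),
        seed=st.integers(0, 10_000),
        threshold=st.sampled_from([0.3, 0.5, 0.9, 1.0]),
    )
    def test_matches_brute_force_oracle(self, n, seed, threshold):
        rng = np.random.default_rng(seed)
        calls = []
        for i in range(n):
            start = int(rng.integers(1, 5_000))
            calls.append(make_call(
                sample=f"S{i}", chrom=str(rng.integers(1, 3)),
                start=start, end=start + int(rng.integers(1, 2_000))))
        assert overlap_counts(calls, threshold) == brute_force_counts(calls, threshold)


class TestIdentifyCommon:
    def _cluster(self, n, start=10_000, length=100_000, cn=1):
        # near-identical calls: small shifts keep pairwise overlap >= 0.5
        return [make_call(sample=f"S{i}", start=start + 100 * i,
                          end=start + 100 * i + length, cn=cn) for i in range(n)]

    def test_four_near_identical_all_common(self):
        common = identify_common(self._cluster(4), RareConfig())
        assert len(common) == 4
        assert all(cc.count == 4 for cc in common)

    def test_three_not_common(self):
        assert identify_common(self._cluster(3), RareConfig()) == []

    def test_types_counted_separately(self):
        calls = self._cluster(2, cn=1) + self._cluster(2, cn=3)
        assert identify_common(calls, RareConfig()) == []

    def test_planted_locus_recovered(self):
        # DERIVED: binomial carrier draw at 10% in a reference of 200
        rng = np.random.default_rng(5)
        carriers = rng.random(200) < 0.1
        calls = [make_call(sample=f"R{i}", start=1_000_000 + int(rng.integers(-5_000, 5_000)),
                           end=1_100_000 + int(rng.integers(-5_000, 5_000)))
                 for i in range(200) if carriers[i]]
        common = identify_common(calls, RareConfig())
        assert len(common) == len(calls)  # every carrier call classified common


class TestSelectReference:
    def _cohort(self, n_ctrl=10):
        recs = [CohortRecord("A1", Phenotype.CASE)]
        recs += [CohortRecord(f"B{i}", Phenotype.CONTROL) for i in range(n_ctrl)]
        return CohortTable(recs)

    def test_seeded_sample_deterministic(self):
        cfg = RareConfig(reference_size=4)
        ids1 = select_reference_controls(self._cohort(), cfg, seed=9)
        ids2 = select_reference_controls(self._cohort(), cfg, seed=9)
        assert ids1 == ids2 and len(ids1) == 4
        assert all(i.startswith("B") for i in ids1)

    def test_explicit_ids_preferred(self):
        cfg = RareConfig(reference_ids=frozenset({"B1", "B2"}))
        assert select_reference_controls(self._cohort(), cfg) == {"B1", "B2"}

    def test_reference_larger_than_pool_errors(self):
        with pytest.raises(ConfigurationError):
            select_reference_controls(self._cohort(3), RareConfig(reference_size=5))

    def test_case_in_reference_errors(self):
        cfg = RareConfig(reference_ids=frozenset({"A1"}))
        with pytest.raises(ConfigurationError):
            select_reference_controls(self._cohort(), cfg)


class TestFilterRare:
    def _cohort(self):
        return CohortTable([
            CohortRecord("A1", Phenotype.CASE),
            CohortRecord("B1", Phenotype.CONTROL),
            CohortRecord("R1", Phenotype.CONTROL, is_reference_control=True),
        ])

    def test_empty_common_set_identity_on_calls(self):
        calls = [make_call(sample="A1"), make_call(sample="R1")]
        rare, removed, cohort2 = filter_rare(calls, [], self._cohort())
        assert [c.sample_id for c in rare] == ["A1"]  # reference sample dropped
        assert removed == []
        assert "R1" not in cohort2

    def test_exact_match_removed(self):
        call = make_call(sample="A1", start=100, end=199)
        common = [CommonCnv("1", 100, 199, CnvType.DEL, 4)]
        rare, removed, _ = filter_rare([call], common, self._cohort())
        assert removed == [call]

    def test_forced_fraction_kept(self):
        # 90 kb of a 200 kb call covered: 0.45 < 0.5
        call = make_call(sample="A1", start=1, end=200_000)
        common = [CommonCnv("1", 1, 90_000, CnvType.DEL, 4)]
        rare, removed, _ = filter_rare([call], common, self._cohort())
        assert rare == [call]

    def test_type_mismatch_never_removes(self):
        call = make_call(sample="A1", start=100, end=199, cn=3)
        common = [CommonCnv("1", 100, 199, CnvType.DEL, 4)]
        rare, _, _ = filter_rare([call], common, self._cohort())
        assert rare == [call]

    def test_anti_monotone_in_common_set(self):
        rng = np.random.default_rng(1)
        calls = [make_call(sample="A1", start=int(s), end=int(s) + 10_000)
                 for s in rng.integers(1, 500_000, 30)]
        small = [CommonCnv("1", 100_000, 120_000, CnvType.DEL, 4)]
        big = small + [CommonCnv("1", 300_000, 320_000, CnvType.DEL, 5)]
        rare_small = filter_rare(calls, small, self._cohort())[0]
        rare_big = filter_rare(calls, big, self._cohort())[0]
        assert set(rare_big) <= set(rare_small)

    def test_query_fraction_asymmetric(self):
        small = make_call(start=100, end=199)
        big = make_call(start=1, end=1000)
        assert query_fraction(small, big) == 1.0
        assert query_fraction(big, small) == pytest.approx(100 / 1000)


class TestCarrierFrequencyTable:
    def test_singleton_frequency(self):
        cohort = CohortTable(
            [CohortRecord(f"S{i}",
                          Phenotype.CASE if i == 0 else Phenotype.CONTROL)
             for i in range(1000)])
        table = carrier_frequency_table([make_call(sample="S0")], cohort)
        assert table["frequency"].tolist() == [0.001]

    def test_empty_rare_set(self, small_cohort):
        assert carrier_frequency_table([], small_cohort).empty

    def test_cross_check_against_identify_common(self, small_cohort):
        # after removing common variants, re-counting on the filtered output
        # never reaches the common threshold again on the same reference
        rng = np.random.default_rng(2)
        cohort = CohortTable(
            [CohortRecord(f"S{i}", Phenotype.CONTROL,
                          is_reference_control=i < 20) for i in range(1, 41)]
            + [CohortRecord("A0", Phenotype.CASE)])
        calls = []
        for i in range(1, 41):
            start = int(rng.choice([10_000, 10_050, 500_000 + 40_000 * i]))
            calls.append(make_call(sample=f"S{i}", start=start, end=start + 20_000))
        cfg = RareConfig(common_min_count=4)
        ref_calls = [c for c in calls if cohort[c.sample_id].is_reference_control]
        common = identify_common(ref_calls, cfg)
        rare, _, cohort2 = filter_rare(calls, common, cohort, cfg)
        recount = identify_common(rare, cfg)
        assert all(cc.count < cfg.common_min_count for cc in recount) or recount == []
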