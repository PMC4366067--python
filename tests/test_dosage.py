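import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ploidosage.core import AnalysisConfig, ContractError, InvalidInputError
from ploidosage.dosage import (
    DosageClassRecord,
    assign_dosage_class,
    classify_records,
    classify_similarity,
    de_exact_test,
    fdr_adjust_dependent,
    tally,
)
from ploidosage.ratios import RatioRecord

from oracles import bh_qvalues, exact_binom_two_sided


class TestClassifySimilarity:
    @pytest.mark.parametrize(
        "fold,expected",
        [(1.0, True), (2.0, False), (0.5, False), (1.99, True), (0.51, True)],
    )
    def test_strict_twofold_threshold(self, fold, expected):
        assert classify_similarity(fold) is expected

    def test_nonpositive_fold_raises(self):
        for bad in (0.0, -1.0, math.nan):
            with pytest.raises(InvalidInputError):
                classify_similarity(bad)


class TestAssignDosageClass:
    @pytest.mark.parametrize(
        "fold,cls",
        [
            (1.0, "I"),
            (1.5, "II"),
            (0.6, "III"),
            (1.9, "IV"),
            # boundary ties: class I closed, class II half-open
            (0.75, "I"),
            (1.25, "I"),
            (1.75, "II"),
        ],
    )
    def test_class_intervals(self, fold, cls):
        assert assign_dosage_class(fold) == cls

    def test_non_se_fold_is_contract_error(self):
        with pytest.raises(ContractError):
            assign_dosage_class(2.5)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=0.501, max_value=1.999))
    def test_every_se_fold_gets_exactly_one_class(self, fold):
        assert assign_dosage_class(fold) in ("I", "II", "III", "IV")


class TestDeExactTest:
    def test_balanced_counts_near_one(self):
        assert de_exact_test(5, 5, 10**6, 10**6) >= 0.99

    def test_ten_vs_zero_equal_libraries(self):
        assert de_exact_test(10, 0, 10**6, 10**6) == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_zero_counts_give_p_one(self):
        assert de_exact_test(0, 0, 10**6, 10**6) == 1.0

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            a, b = rng.integers(0, 200, size=2)
            la, lb = rng.integers(10**5, 10**7, size=2)
            assert de_exact_test(a, b, la, lb) == pytest.approx(
                de_exact_test(b, a, lb, la), abs=1e-12
            )

    @pytest.mark.parametrize("share", [0.5, 0.3])
    def test_matches_enumeration_oracle_small_n(self, share):
        lib_a = int(share * 10**6)
        lib_b = 10**6 - lib_a
        for n in range(1, 26):
            for k in range(n + 1):
                got = de_exact_test(k, n - k, lib_a, lib_b)
                want = exact_binom_two_sided(k, n, lib_a / (lib_a + lib_b))
                assert got == pytest.approx(want, rel=1e-9), (k, n, share)

    def test_invalid_library_sizes_raise(self):
        with pytest.raises(InvalidInputError):
            de_exact_test(1, 1, 0, 10)


class TestFdrAdjustDependent:
    def test_single_p_unchanged(self):
        assert fdr_adjust_dependent([0.04]) == pytest.approx([0.04])

    def test_three_p_hand_computed(self):
        # m=3, c(3)=11/6; all step-up values collapse to 0.01 * 3 * (11/6) = 0.055
        got = fdr_adjust_dependent([0.01, 0.02, 0.03])
        assert got == pytest.approx([0.055, 0.055, 0.055], abs=1e-12)

    def test_all_ones_stay_ones(self):
        assert fdr_adjust_dependent([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_p_raises(self):
        with pytest.raises(InvalidInputError):
            fdr_adjust_dependent([0.5, 1.5])

    def test_monotone_in_sorted_order_and_dominates_bh(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(2, 60))
            q = fdr_adjust_dependent(p)
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-15)
            assert np.all(q >= np.asarray(bh_qvalues(list(p))) - 1e-12)

    def test_matches_statsmodels_by(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        _, q_sm, _, _ = multipletests(p, method="fdr_by")
        np.testing.assert_allclose(fdr_adjust_dependent(p), q_sm, rtol=1e-10)


def _ratio(gene, fold):
    return RatioRecord(gene, fold, 1.0, fold, math.log2(fold))


class TestClassifyRecordsAndTally:
    def test_se_and_de_are_independent_calls(self):
        ratios = [_ratio("g_se_de", 1.9), _ratio("g_neither", 2.5), _ratio("g_se", 1.0)]
        recs = classify_records(
            ratios,
            numerator_counts={"g_se_de": 2000, "g_neither": 10, "g_se": 1000},
            denominator_counts={"g_se_de": 1000, "g_neither": 11, "g_se": 1000},
            libsize_numerator=10**6,
            libsize_denominator=10**6,
        )
        by = {r.gene_id: r for r in recs}
        assert by["g_se_de"].se_flag and by["g_se_de"].de_flag
        assert by["g_se_de"].de_direction == "higher_in_triploid"
        assert not by["g_neither"].se_flag and not by["g_neither"].de_flag
        assert by["g_se"].se_flag and not by["g_se"].de_flag
        assert by["g_neither"].dosage_class == "NA"

    def test_single_se_gene_tally(self):
        recs = [DosageClassRecord("g1", 1.0, True, "I")]
        t = tally(recs)
        assert t.per_class == {"I": 1, "II": 0, "III": 0, "IV": 0}
        assert t.pct_class_of_se["I"] == 100

    @pytest.mark.parametrize(
        "counts,expected_pct",
        [
            # SE class counts -> integer percentages of SE
            ({"I": 26376, "II": 9935, "III": 19672, "IV": 2093},
             {"I": 45, "II": 17, "III": 34, "IV": 4}),
            ({"I": 3508, "II": 1308, "III": 4947, "IV": 305},
             {"I": 35, "II": 13, "III": 49, "IV": 3}),
        ],
    )
    def test_percentage_arithmetic_on_published_class_counts(self, counts, expected_pct):
        fold_by_class = {"I": 1.0, "II": 1.5, "III": 0.6, "IV": 1.9}
        recs = [
            DosageClassRecord(f"{cls}_{i}", fold_by_class[cls], True, cls)
            for cls, n in counts.items()
            for i in range(n)
        ]
        t = tally(recs)
        assert t.n_se == sum(counts.values())
        assert t.pct_class_of_se == expected_pct

    def test_de_group_percentages(self):
        recs = [
            DosageClassRecord(f"h{i}", 2.5, False, "NA", de_flag=True,
                              de_direction="higher_in_triploid")
            for i in range(6813)
        ] + [
            DosageClassRecord(f"l{i}", 0.3, False, "NA", de_flag=True,
                              de_direction="lower_in_triploid")
            for i in range(13655)
        ]
        t = tally(recs)
        assert t.n_de == 20468
        assert t.pct_group_of_de == {"DEH": 33, "DEL": 67}

    def test_empty_tally_raises(self):
        with pytest.raises(InvalidInputError):
            tally([])
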