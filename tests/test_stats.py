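import datetime as dt

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from readbridge.io import ClinicalEvent, MappingRecord
from readbridge.stats import (
    AgreementClass,
    CurationVerdict,
    QualityCategory,
    QualityGroup,
    assign_quality_category,
    compare_mappings,
    group_report,
    prevalence_count,
    proportion_ci,
    quality_report,
    round_pct,
)
from readbridge.terminology import CodeSystem


def icd(code):
    return (code, CodeSystem.ICD10CM)


class TestQualityCategory:
    def test_single_precise_target_is_perfect(self):
        got = assign_quality_category([icd("A080")], CurationVerdict(precise=True))
        assert got is QualityCategory.PERFECT

    def test_two_targets_are_a_combination(self):
        got = assign_quality_category(
            [icd("K620"), icd("K621")], CurationVerdict(precise=False)
        )
        assert got is QualityCategory.MULTIPLE_COMBINATION

    def test_block_range_target(self):
        got = assign_quality_category(
            [icd("H80-H83")], CurationVerdict(precise=False)
        )
        assert got is QualityCategory.MULTIPLE_BLOCK

    def test_morphology_target_dominates(self):
        got = assign_quality_category(
            [icd("C413"), ("8070/3", CodeSystem.ICDO3)],
            CurationVerdict(precise=False),
        )
        assert got is QualityCategory.MULTIPLE_MORPHOLOGY

    @pytest.mark.parametrize(
        "verdict, expected",
        [
            (CurationVerdict(precise=False, unspecified_qualifier=True),
             QualityCategory.IMPRECISE_UNSPECIFIED),
            (CurationVerdict(precise=False, closest_only=True),
             QualityCategory.IMPRECISE_CLOSEST),
            (CurationVerdict(precise=False),
             QualityCategory.IMPRECISE_GENERAL),
        ],
    )
    def test_imprecision_subtypes(self, verdict, expected):
        assert assign_quality_category([icd("B069")], verdict) is expected

    def test_groups_follow_the_taxonomy(self):
        assert QualityCategory.PERFECT.group is QualityGroup.NO_ISSUE
        for cat in (
            QualityCategory.IMPRECISE_GENERAL,
            QualityCategory.IMPRECISE_CLOSEST,
            QualityCategory.IMPRECISE_UNSPECIFIED,
        ):
            assert cat.group is QualityGroup.IMPRECISE
        for cat in (
            QualityCategory.MULTIPLE_COMBINATION,
            QualityCategory.MULTIPLE_MORPHOLOGY,
            QualityCategory.MULTIPLE_BLOCK,
        ):
            assert cat.group is QualityGroup.MULTIPLE


def record(code, targets, system=CodeSystem.ICD10):
    return MappingRecord(
        read_code=code,
        read_version=CodeSystem.READ3,
        targets=[(t, system) for t in targets],
    )


class TestCompareMappings:
    def test_identical_sets_are_exact(self):
        assert (
            compare_mappings(record("A0762", ["A080"]), record("A0762", ["A080"]))
            is AgreementClass.EXACT
        )

    def test_partial_multi_when_extra_wrong_targets(self):
        auto = record("A0762", ["A080", "J108", "J118"])
        manual = record("A0762", ["A080"])
        assert compare_mappings(auto, manual) is AgreementClass.PARTIAL_MULTI

    def test_empty_auto_is_missing(self):
        auto = record("SN580", [])
        manual = record("SN580", ["Z91012"])
        assert compare_mappings(auto, manual) is AgreementClass.MISSING_OR_INCORRECT

    def test_morphology_dominates(self):
        manual = MappingRecord(
            read_code="B1234",
            read_version=CodeSystem.READ3,
            targets=[("8070/3", CodeSystem.ICDO3)],
        )
        assert (
            compare_mappings(record("B1234", []), manual) is AgreementClass.MORPHOLOGY
        )

    def test_match4_on_four_character_prefix(self):
        auto, manual = record("Xa2Tq", ["W540XXA"]), record("Xa2Tq", ["W540"])
        assert compare_mappings(auto, manual) is AgreementClass.MATCH4

    def test_match3_on_category_agreement(self):
        auto, manual = record("G2y..", ["I158"]), record("G2y..", ["I159"])
        assert compare_mappings(auto, manual) is AgreementClass.MATCH3

    def test_near_miss_when_nothing_agrees(self):
        auto, manual = record("X....", ["T781"]), record("X....", ["Z9101"])
        assert compare_mappings(auto, manual) is AgreementClass.NEAR_MISS

    def test_comparing_record_with_itself_is_exact(self):
        rec = record("XE1DV", ["M190", "M199"])
        assert compare_mappings(rec, rec) is AgreementClass.EXACT

    def test_different_codes_rejected(self):
        with pytest.raises(ValueError):
            compare_mappings(record("A....", ["A00"]), record("B....", ["A00"]))


class TestProportionCI:
    def test_printed_interval_reproduction(self):
        ci = proportion_ci(796, 1313)
        assert round(ci.pct, 1) == 60.6
        assert (round(ci.lower, 1), round(ci.upper, 1)) == (58.0, 63.2)
        ci = proportion_ci(439, 1313)
        assert round(ci.pct, 1) == 33.4
        assert (round(ci.lower, 1), round(ci.upper, 1)) == (30.9, 36.0)

    def test_boundary_counts(self):
        ci = proportion_ci(0, 10)
        assert ci.pct == 0.0 and ci.lower >= 0.0
        ci = proportion_ci(10, 10)
        assert ci.pct == 100.0 and ci.upper <= 100.0

    def test_domain_violations_rejected(self):
        for k, n, level in [(-1, 10, 0.95), (11, 10, 0.95), (1, 0, 0.95),
                            (1, 10, 1.0)]:
            with pytest.raises(ValueError):
                proportion_ci(k, n, level)

    @given(st.integers(0, 50), st.integers(1, 4))
    def test_interval_contains_point_estimate(self, k, extra):
        n = k + extra * 10 + 1
        ci = proportion_ci(k, n)
        assert 0.0 <= ci.lower <= ci.upper <= 100.0
        # flat prior pulls toward 50% but the interval still covers k/n for
        # non-degenerate counts
        assert ci.lower <= max(ci.pct, 100.0 / (n + 2)) + 1e-9

    def test_width_shrinks_with_n_at_fixed_ratio(self):
        widths = []
        for n in (10, 100, 1000, 10000):
            ci = proportion_ci(int(0.3 * n), n)
            widths.append(ci.upper - ci.lower)
        assert widths == sorted(widths, reverse=True)

    def test_agrees_with_posterior_sampling_oracle(self):
        rng = np.random.default_rng(20201)
        for k, n in [(796, 1313), (78, 1313), (3, 10)]:
            draws = rng.beta(k + 1, n - k + 1, size=10 ** 6) * 100
            lo, hi = np.quantile(draws, [0.025, 0.975])
            ci = proportion_ci(k, n)
            assert ci.lower == pytest.approx(lo, abs=0.1)
            assert ci.upper == pytest.approx(hi, abs=0.1)


class TestQualityReport:
    def test_single_category_is_one_row_at_100(self):
        table = quality_report([QualityCategory.PERFECT] * 4)
        assert len(table) == 1
        assert table.loc[0, "pct"] == 100.0
        assert table.loc[0, "group"] == "NO_ISSUE"

    def test_row_order_and_percentages_from_exact_counts(self):
        labels = (
            [QualityCategory.PERFECT] * 796
            + [QualityCategory.IMPRECISE_GENERAL] * 413
            + [QualityCategory.MULTIPLE_COMBINATION] * 36
            + [QualityCategory.MULTIPLE_MORPHOLOGY] * 27
            + [QualityCategory.IMPRECISE_CLOSEST] * 16
            + [QualityCategory.MULTIPLE_BLOCK] * 15
            + [QualityCategory.IMPRECISE_UNSPECIFIED] * 10
        )
        assert len(labels) == 1313
        table = quality_report(labels)
        assert list(table["count"]) == [796, 413, 36, 27, 16, 15, 10]
        assert list(table["pct"])[:2] == [60.6, 31.5]  # half-up rounding
        truncated = quality_report(labels, rounding="truncate")
        assert list(truncated["pct"])[:2] == [60.6, 31.4]

    def test_percentages_sum_to_100_within_rounding_slack(self):
        labels = [QualityCategory.PERFECT] * 7 + [QualityCategory.MULTIPLE_BLOCK] * 3
        table = quality_report(labels)
        assert abs(table["pct"].sum() - 100.0) <= 0.1 * len(table)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            quality_report([])

    def test_group_report_aggregates_categories(self):
        labels = [
            QualityCategory.PERFECT,
            QualityCategory.IMPRECISE_GENERAL,
            QualityCategory.IMPRECISE_CLOSEST,
            QualityCategory.MULTIPLE_BLOCK,
        ]
        table = group_report(labels).set_index("group")
        assert table.loc["IMPRECISE", "count"] == 2
        assert table.loc["NO_ISSUE", "pct"] == 25.0


def test_round_pct_modes():
    assert round_pct(31.45, "half-up") == 31.5
    assert round_pct(31.45, "truncate") == 31.4
    with pytest.raises(ValueError):
        round_pct(1.0, "bankers")


class TestPrevalenceCount:
    def events(self, rows):
        return [
            ClinicalEvent(
                eid=eid,
                data_provider=1,
                event_dt=dt.date(2005, 1, 1),
                read_2=code if version is CodeSystem.READ2 else None,
                read_3=code if version is CodeSystem.READ3 else None,
            )
            for eid, code, version in rows
        ]

    def test_no_events_counts_zero(self):
        assert prevalence_count([], [record("X....", ["E702"])], "E70") == 0

    def test_distinct_participants_counted_once(self):
        events = self.events([("1", "XE1DV", CodeSystem.READ3)] * 5)
        mapping = [record("XE1DV", ["E702"])]
        assert prevalence_count(events, mapping, "E70") == 1

    def test_prefix_truncation_matches_any_target(self):
        events = self.events(
            [("1", "XE1DV", CodeSystem.READ3), ("2", "N05..", CodeSystem.READ2)]
        )
        mapping = [
            record("XE1DV", ["M190", "E702"]),
            MappingRecord(
                read_code="N05..",
                read_version=CodeSystem.READ2,
                targets=[("M199", CodeSystem.ICD10)],
            ),
        ]
        assert prevalence_count(events, mapping, "E70") == 1
        assert prevalence_count(events, mapping, "M19") == 2

    def test_version_mismatch_does_not_count(self):
        # the same code string under the other Read version must not match
        events = self.events([("1", "XE1DV", CodeSystem.READ2)])
        mapping = [record("XE1DV", ["E702"])]  # a READ3 record
        assert prevalence_count(events, mapping, "E70") == 0
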