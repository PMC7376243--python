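"""Gestational arithmetic, analysis sets, cohort summaries, comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vocptb.cohort import (
    CohortSummary,
    DeliveryCategory,
    GestationalAge,
    Patient,
    Swab,
    build_analysis_set,
    categorize_delivery,
    compare_groups,
    format_gestation_days,
    median_iqr,
    parse_gestation,
    read_cohort,
    select_analysis_swab,
    summarize_cohort,
    write_cohort,
)


def swab(pid, sid, days, bv="negative"):
    return Swab(pid, sid, GestationalAge(days), bv)


def patient(pid, swab_days, delivery_days=None, outcome="spontaneous", bv_days=()):
    swabs = [
        swab(pid, f"{pid}s{i}", d, "positive" if d in bv_days else "negative")
        for i, d in enumerate(swab_days)
    ]
    return Patient(
        patient_id=pid,
        swabs=swabs,
        gestation_at_delivery=GestationalAge(delivery_days) if delivery_days else None,
        outcome=outcome,
    )


class TestGestation:
    @pytest.mark.parametrize("text,days", [("17 + 4", 123), ("37 + 0", 259), ("0 + 6", 6)])
    def test_parse_weeks_plus_days(self, text, days):
        assert parse_gestation(text).days == days

    @pytest.mark.parametrize("text", ["16 + 9", "-1 + 2", "17", "abc", "3 + -1"])
    def test_invalid_notation_rejected(self, text):
        with pytest.raises(ValueError):
            parse_gestation(text)

    def test_round_trip_with_formatting(self):
        assert str(parse_gestation("31 + 6")) == "31 + 6"
        assert format_gestation_days(123.4) == "17 + 4"

    @pytest.mark.parametrize(
        "days,category",
        [
            (167, DeliveryCategory.MIDTRIMESTER_MISCARRIAGE),
            (168, DeliveryCategory.EXTREME_PRETERM),
            (195, DeliveryCategory.EXTREME_PRETERM),
            (196, DeliveryCategory.VERY_PRETERM),
            (223, DeliveryCategory.VERY_PRETERM),
            (224, DeliveryCategory.LATE_PRETERM),
            (258, DeliveryCategory.LATE_PRETERM),
            (259, DeliveryCategory.TERM),
        ],
    )
    def test_delivery_category_boundaries(self, days, category):
        assert categorize_delivery(GestationalAge(days)) is category

    @settings(derandomize=True, deadline=None)
    @given(st.integers(0, 330))
    def test_categories_partition_all_gestations(self, days):
        cat = categorize_delivery(GestationalAge(days))
        assert isinstance(cat, DeliveryCategory)
        assert (cat is DeliveryCategory.TERM) == (days >= 259)


class TestSwabSelection:
    def test_first_and_closest_modes(self):
        p = patient("p1", [105, 140, 182], delivery_days=238)
        assert select_analysis_swab(p, "first").gestation_at_sampling.days == 105
        assert select_analysis_swab(p, "closest_to_delivery").gestation_at_sampling.days == 182

    def test_tie_broken_by_stored_order(self):
        p = patient("p1", [126, 126], delivery_days=260)
        assert select_analysis_swab(p, "first").sample_id == "p1s0"

    def test_no_swabs_rejected(self):
        p = Patient("p0", [], outcome="unknown")
        with pytest.raises(ValueError, match="no swabs"):
            select_analysis_swab(p, "first")


class TestAnalysisSets:
    def build_cohort(self):
        patients = []
        for i in range(196):
            preterm = i < 39
            patients.append(
                patient(f"sp{i}", [100 + i % 50], delivery_days=230 if preterm else 270)
            )
        for i in range(11):
            patients.append(
                patient(f"ia{i}", [120], delivery_days=240, outcome="iatrogenic")
            )
        for i in range(9):
            patients.append(patient(f"uk{i}", [120], outcome="unknown"))
        return patients

    def test_preterm_set_excludes_iatrogenic_and_unknown(self):
        patients = self.build_cohort()
        ids, labels = build_analysis_set(patients, "preterm", "first")
        assert len(ids) == 196  # 216 minus 11 iatrogenic minus 9 unknown
        assert labels.sum() == 39
        bv_ids, _ = build_analysis_set(patients, "bv", "first")
        assert len(bv_ids) == 216  # everyone keeps a BV label

    def test_all_unknown_outcomes_rejected_for_preterm(self):
        patients = [patient(f"u{i}", [120], outcome="unknown") for i in range(5)]
        with pytest.raises(ValueError, match="empty"):
            build_analysis_set(patients, "preterm", "first")

    def test_bv_label_is_any_positive_swab(self):
        p = patient("p", [100, 150], delivery_days=270, bv_days=(150,))
        _, labels = build_analysis_set([p], "bv", "first")
        assert labels.tolist() == [1]


class TestCohortSummary:
    def test_published_counts_reproduce_reported_percentages(self):
        s = CohortSummary.from_counts(
            bv_positive=(26, 216),
            preterm=(39, 196),
            before_32_weeks=(18, 196),
            preterm_given_bv_positive=(13, 22),
            preterm_given_bv_negative=(25, 174),
        )
        assert s.bv_positive.pct == 12.0
        assert s.preterm.pct == 19.9
        assert s.preterm_given_bv_positive.pct == 59.1
        assert s.preterm_given_bv_negative.pct == 14.4
        assert s.before_32_weeks.pct == 9.2

    def test_percentages_round_half_up(self):
        assert CohortSummary.from_counts((1, 8), (0, 1), (0, 1), (0, 1), (0, 1)).bv_positive.pct == 12.5
        assert CohortSummary.from_counts((5, 40), (0, 1), (0, 1), (0, 1), (0, 1)).bv_positive.pct == 12.5
        # 0.05% boundary rounds up, not to even
        assert CohortSummary.from_counts((9, 8000), (0, 1), (0, 1), (0, 1), (0, 1)).bv_positive.pct == 0.1

    def test_patient_level_summary_counts(self):
        patients = [
            patient("a", [100], delivery_days=230, bv_days=(100,)),  # BV+, preterm
            patient("b", [100], delivery_days=270, bv_days=(100,)),  # BV+, term
            patient("c", [100], delivery_days=220),                  # BV-, preterm <32w
            patient("d", [100], delivery_days=270),
            patient("e", [100], outcome="unknown"),
        ]
        s = summarize_cohort(patients)
        assert (s.bv_positive.count, s.bv_positive.denominator) == (2, 5)
        assert (s.preterm.count, s.preterm.denominator) == (2, 4)
        assert (s.before_32_weeks.count, s.before_32_weeks.denominator) == (1, 4)
        assert (s.preterm_given_bv_positive.count, s.preterm_given_bv_positive.denominator) == (1, 2)
        assert (s.preterm_given_bv_negative.count, s.preterm_given_bv_negative.denominator) == (1, 2)

    def test_quiet_cohort_is_all_zero_without_errors(self):
        patients = [patient(f"p{i}", [100], delivery_days=270) for i in range(10)]
        s = summarize_cohort(patients)
        assert s.bv_positive.pct == 0.0 and s.preterm.pct == 0.0

    def test_single_patient_flags_tiny_denominators(self):
        p = patient("solo", [100], delivery_days=230, bv_days=(100,))
        with pytest.warns(UserWarning):
            s = summarize_cohort([p])
        assert s.preterm_given_bv_positive.pct == 100.0


class TestGroupComparisons:
    def test_identical_groups_not_significant(self):
        res = compare_groups(
            np.array([1.0, 2, 3, 1, 2, 3]), np.array(["a"] * 3 + ["b"] * 3)
        )
        assert res.p_value == pytest.approx(1.0)

    def test_chi_square_without_continuity_correction(self):
        values = np.array(["x"] * 20 + ["y"] * 10 + ["x"] * 10 + ["y"] * 20)
        groups = np.array(["g1"] * 30 + ["g2"] * 30)
        res = compare_groups(values, groups, categorical=True)
        assert res.test == "chi_square"
        assert res.statistic == pytest.approx(20 / 3, abs=1e-9)  # sum (O-E)^2/E = 6.667

    def test_normal_data_takes_t_branch(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(0, 1, 40), rng.normal(0.2, 1, 40)])
        groups = np.array([0] * 40 + [1] * 40)
        res = compare_groups(values, groups)
        assert res.test == "t_test"
        assert "mean" in res.summaries[0]

    def test_skewed_data_takes_mann_whitney_branch(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.exponential(1, 50), rng.exponential(1, 50)])
        groups = np.array([0] * 50 + [1] * 50)
        res = compare_groups(values, groups)
        assert res.test == "mann_whitney"
        assert res.p_value > 0.001
        assert "median" in res.summaries[0]

    def test_zero_variance_both_groups_degenerate(self):
        res = compare_groups(np.array([2.0] * 6), np.array([0, 0, 0, 1, 1, 1]))
        assert res.test == "degenerate" and res.p_value == 1.0

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            compare_groups(np.array([1.0, 2.0, 3.0, 4.0]), np.array([0, 0, 0, 1]))


class TestMedianIQR:
    def test_gestational_median_renders_back(self):
        med, q1, q3 = median_iqr([GestationalAge(118), GestationalAge(123), GestationalAge(150)])
        assert med == 123 and format_gestation_days(med) == "17 + 4"

    def test_single_value_collapses(self):
        assert median_iqr([5.0]) == (5.0, 5.0, 5.0)

    def test_linear_interpolation_convention(self):
        med, q1, q3 = median_iqr([1, 2, 3, 4])
        assert med == 2.5
        # oracle: numpy's linear (type-7) definition computed by hand:
        # q1 at position 0.75 between 1 and 2; q3 at 2.25 between 3 and 4
        assert q1 == pytest.approx(1.75) and q3 == pytest.approx(3.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])


def test_cohort_csv_round_trip(tmp_path):
    patients = [
        patient("a", [100, 150], delivery_days=230, bv_days=(100,)),
        patient("b", [110], outcome="unknown"),
        Patient(
            "c",
            swabs=[swab("c", "cs0", 120)],
            age_years=31.5,
            bmi=24.0,
            smoking="no",
            gestation_at_delivery=GestationalAge(270),
            outcome="spontaneous",
        ),
    ]
    write_cohort(patients, tmp_path / "patients.csv", tmp_path / "swabs.csv")
    back = read_cohort(tmp_path / "patients.csv", tmp_path / "swabs.csv")
    assert [p.patient_id for p in back] == ["a", "b", "c"]
    assert back[0].bv_positive and back[0].gestation_at_delivery.days == 230
    assert back[1].outcome == "unknown" and back[1].gestation_at_delivery is None
    assert back[2].age_years == 31.5
    assert [s.sample_id for s in back[0].swabs] == ["as0", "as1"]
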