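"""Risk banding, crossing statistics, and range summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_cohort
from lipidrhythm import (
    Analyte,
    RiskScheme,
    classify,
    crossing_report,
    variability_summary,
)

SCHEME = RiskScheme.ncep_default()


def linear_scan_classify(boundaries, labels, value):
    """Independent oracle: walk the bands left to right."""
    for i, b in enumerate(boundaries):
        if value < b:
            return labels[i]
    return labels[-1]


class TestClassify:
    def test_tc_below_200_is_first_band(self):
        assert classify(SCHEME, Analyte.TC, 195.0) == "desirable"

    def test_boundary_value_joins_higher_band(self):
        assert classify(SCHEME, Analyte.TC, 200.0) == "borderline-high"

    @pytest.mark.parametrize("analyte", list(Analyte))
    def test_matches_linear_scan_oracle_on_grid(self, analyte):
        bs = SCHEME.boundaries[analyte]
        labels = SCHEME.labels[analyte]
        for value in np.arange(1.0, 601.0, 1.0):
            assert classify(SCHEME, analyte, value) == linear_scan_classify(
                bs, labels, value
            )

    @given(v=st.floats(1.0, 1999.0))
    def test_monotone_in_value(self, v):
        lo = SCHEME.category_index(Analyte.TG, v)
        hi = SCHEME.category_index(Analyte.TG, v + 1.0)
        assert lo <= hi

    def test_unknown_analyte_and_nonpositive_value_rejected(self):
        scheme = RiskScheme(
            boundaries={Analyte.TC: (200.0,)}, labels={Analyte.TC: ("a", "b")}
        )
        with pytest.raises(ValueError):
            scheme.classify(Analyte.TG, 100.0)
        with pytest.raises(ValueError):
            scheme.classify(Analyte.TC, 0.0)

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            RiskScheme(
                boundaries={Analyte.TC: (240.0, 200.0)},
                labels={Analyte.TC: ("a", "b", "c")},
            )
        with pytest.raises(ValueError):
            RiskScheme(boundaries={Analyte.TC: (200.0,)}, labels={Analyte.TC: ("a",)})


def within_day(pid, values, analyte="TC", day=1):
    return [
        (f"2024-01-{day:02d} {6 + 2 * i:02d}:00", analyte, v)
        for i, v in enumerate(values)
    ]


class TestCrossingReport:
    def test_two_band_day_crosses(self):
        cohort = make_cohort({"P01": within_day("P01", [180.0, 210.0])})
        rep = crossing_report(cohort, SCHEME, "within_day")
        row = rep.rows.iloc[0]
        assert row["n_categories"] == 2 and bool(row["crossed"])
        assert row["range"] == pytest.approx(30.0)

    def test_single_band_day_does_not_cross(self):
        cohort = make_cohort({"P01": within_day("P01", [180.0, 185.0, 190.0])})
        rep = crossing_report(cohort, SCHEME, "within_day")
        assert not rep.rows.iloc[0]["crossed"]

    def test_designed_crossing_percentage_recovered_exactly(self):
        # 9 of 20 participants constructed to straddle the 200 mg/dL split
        spec = {}
        for i in range(20):
            pid = f"P{i + 1:02d}"
            values = [190.0, 195.0, 205.0, 210.0] if i < 9 else [180.0, 185.0, 190.0, 195.0]
            spec[pid] = within_day(pid, values)
        rep = crossing_report(make_cohort(spec), SCHEME, "within_day")
        assert rep.percent_crossed(Analyte.TC) == pytest.approx(45.0)
        assert rep.denominator(Analyte.TC) == 20

    def test_crossing_requires_single_day_not_across_days(self):
        # each day sits in one band; bands differ between days
        cohort = make_cohort(
            {"P01": within_day("P01", [180.0, 190.0], day=1) + within_day("P01", [210.0, 220.0], day=2)}
        )
        rep = crossing_report(cohort, SCHEME, "within_day")
        assert not rep.rows.iloc[0]["crossed"]

    def test_across_mornings_grouping(self):
        cohort = make_cohort(
            {
                "P01": [
                    ("2024-01-01 06:30", "TC", 195.0, {"fasted": True}),
                    ("2024-01-02 06:30", "TC", 205.0, {"fasted": True}),
                    ("2024-01-03 09:00", "TC", 300.0, {"fasted": True}),  # out of window
                ]
            }
        )
        rep = crossing_report(cohort, SCHEME, "across_mornings")
        row = rep.rows.iloc[0]
        assert row["n_samples"] == 2 and bool(row["crossed"])

    def test_under_sampled_participants_excluded_from_denominator(self):
        cohort = make_cohort(
            {
                "P01": within_day("P01", [180.0, 210.0]),
                "P02": [("2024-01-01 08:00", "TC", 300.0)],  # a single sample
            }
        )
        rep = crossing_report(cohort, SCHEME, "within_day")
        assert rep.denominator(Analyte.TC) == 1
        assert ("P02", "TC", "<2 qualifying samples") in rep.excluded
        assert rep.percent_crossed(Analyte.TC) == pytest.approx(100.0)

    def test_union_percentages(self):
        cohort = make_cohort(
            {
                "P01": within_day("P01", [195.0, 205.0]) + within_day("P01", [55.0, 58.0], "HDL"),
                "P02": within_day("P02", [180.0, 185.0]) + within_day("P02", [38.0, 42.0], "HDL"),
                "P03": within_day("P03", [170.0, 175.0]) + within_day("P03", [50.0, 52.0], "HDL"),
            }
        )
        rep = crossing_report(cohort, SCHEME, "within_day")
        assert rep.percent_crossed(Analyte.TC) == pytest.approx(100.0 / 3)
        assert rep.percent_crossed_union([Analyte.TC, Analyte.HDL]) == pytest.approx(200.0 / 3)

    def test_order_duplication_and_relabeling_invariance(self):
        base = {"P01": within_day("P01", [180.0, 210.0, 195.0])}
        shuffled = {"P01": list(reversed(base["P01"]))}
        r1 = crossing_report(make_cohort(base), SCHEME, "within_day")
        r2 = crossing_report(make_cohort(shuffled), SCHEME, "within_day")
        assert r1.percent_crossed(Analyte.TC) == r2.percent_crossed(Analyte.TC)
        relabeled = {"ZZ9": within_day("ZZ9", [180.0, 210.0, 195.0])}
        r3 = crossing_report(make_cohort(relabeled), SCHEME, "within_day")
        assert r1.percent_crossed(Analyte.TC) == r3.percent_crossed(Analyte.TC)

    def test_adding_a_sample_never_shrinks_categories(self):
        before = crossing_report(
            make_cohort({"P01": within_day("P01", [180.0, 210.0])}), SCHEME, "within_day"
        )
        after = crossing_report(
            make_cohort({"P01": within_day("P01", [180.0, 210.0, 245.0])}),
            SCHEME,
            "within_day",
        )
        assert (
            after.rows.iloc[0]["n_categories"] >= before.rows.iloc[0]["n_categories"]
        )

    def test_empty_cohort_yields_empty_report(self):
        from lipidrhythm import CohortTable

        rep = crossing_report(CohortTable(()), SCHEME, "within_day")
        assert len(rep.rows) == 0
        assert np.isnan(rep.percent_crossed(Analyte.TC))


class TestVariabilitySummary:
    def test_identical_ranges(self):
        spec = {
            f"P{i:02d}": within_day(f"P{i:02d}", [180.0, 210.0]) for i in range(1, 6)
        }
        rep = crossing_report(make_cohort(spec), SCHEME, "within_day")
        summary = variability_summary(rep)
        tc = summary[summary["analyte"] == "TC"].iloc[0]
        assert tc["median_range"] == pytest.approx(30.0)
        assert tc["sd_range"] == pytest.approx(0.0)

    def test_median_of_skewed_ranges(self):
        spec = {
            "P01": within_day("P01", [100.0, 110.0]),
            "P02": within_day("P02", [100.0, 120.0]),
            "P03": within_day("P03", [100.0, 190.0]),
        }
        rep = crossing_report(make_cohort(spec), SCHEME, "within_day")
        summary = variability_summary(rep)
        tc = summary[summary["analyte"] == "TC"].iloc[0]
        assert tc["median_range"] == pytest.approx(20.0)
        # order-statistics oracle: SD of {10,20,90} by direct formula
        assert tc["sd_range"] == pytest.approx(float(np.std([10, 20, 90], ddof=1)))

    def test_ranges_match_sort_oracle_on_synthetic_cohort(self):
        from lipidrhythm import SimConfig, generate_cohort

        cohort, _ = generate_cohort(SimConfig(n_participants=6, seed=5))
        rep = crossing_report(cohort, SCHEME, "within_day")
        for _, row in rep.rows.iterrows():
            series = cohort.get(row["participant"])
            vals = sorted(
                s.value for s in series.of_analyte(Analyte(row["analyte"]))
            )
            assert row["range"] == pytest.approx(vals[-1] - vals[0])

    def test_empty_report_rejected(self):
        from lipidrhythm import CohortTable

        rep = crossing_report(CohortTable(()), SCHEME, "within_day")
        with pytest.raises(ValueError):
            variability_summary(rep)
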