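"""Audit tests: cohort filters, completeness tallies and concordance rules
on hand-constructed visit fixtures."""

import datetime as dt

import pandas as pd
import pytest

from pdcgrowth.assessment import assess_cohort
from pdcgrowth.audit import (AuditConfig, apply_cohort_filters, completeness,
                             concordance, round_half_up)
from pdcgrowth.reference import interpolate_lms, inverse_zscore

PRE_DATE = pd.Timestamp("2017-10-01")
POST_DATE = pd.Timestamp("2018-10-01")


def mk_children(rows):
    base = {"sex": "male", "gestational_age_weeks": 40.0,
            "referred_as_preterm": 0, "birthweight_g": 3000,
            "facility_id": "f1", "facility_type": "hospital",
            "arm": "intervention"}
    out = []
    for r in rows:
        d = dict(base)
        d.update(r)
        d.setdefault("birth_date", PRE_DATE - pd.Timedelta(days=30))
        d.setdefault("enrollment_date", d["birth_date"] + pd.Timedelta(days=7))
        out.append(d)
    return pd.DataFrame(out)


def mk_visits(rows):
    base = {"visit_type": "standard_growth", "weight_g": None, "length_cm": None,
            "nurse_corrected_age_recorded": 0, "nurse_lhfa": None,
            "nurse_wflh": None, "nurse_wfa": None, "nurse_interval_growth": None}
    out = []
    for r in rows:
        d = dict(base)
        d.update(r)
        out.append(d)
    return pd.DataFrame(out)


def weight_at_z(refs, z, age_days, sex="male"):
    L, M, S = interpolate_lms(refs.get("weight_for_age", sex), age_days)
    return inverse_zscore(z, L, M, S) * 1000.0


def length_at_z(refs, z, age_days, sex="male"):
    L, M, S = interpolate_lms(refs.get("length_for_age", sex), age_days)
    return inverse_zscore(z, L, M, S)


class TestCohortFilters:
    def test_contaminated_post_visits_of_pre_enrollees_dropped(self):
        children = mk_children([
            {"child_id": "pre_kid", "birth_date": pd.Timestamp("2017-09-01"),
             "enrollment_date": pd.Timestamp("2017-09-10")},
            {"child_id": "post_kid", "birth_date": pd.Timestamp("2018-09-01"),
             "enrollment_date": pd.Timestamp("2018-09-10")},
        ])
        visits = mk_visits(
            [{"child_id": "pre_kid", "visit_date": PRE_DATE + pd.Timedelta(days=i)}
             for i in range(4)]
            + [{"child_id": "pre_kid", "visit_date": POST_DATE + pd.Timedelta(days=i)}
               for i in range(3)]                                 # contaminated
            + [{"child_id": "post_kid", "visit_date": POST_DATE + pd.Timedelta(days=i)}
               for i in range(3)])                                # retained
        got = apply_cohort_filters(visits, children)
        assert len(got) == 7
        assert (got.loc[got["period"] == "post", "child_id"] == "post_kid").all()

    def test_orphans_and_out_of_window_visits_dropped(self):
        children = mk_children([{"child_id": "a",
                                 "birth_date": pd.Timestamp("2017-09-01"),
                                 "enrollment_date": pd.Timestamp("2017-09-08")}])
        visits = mk_visits([
            {"child_id": "a", "visit_date": PRE_DATE},
            {"child_id": "ghost", "visit_date": PRE_DATE},
            {"child_id": "a", "visit_date": pd.Timestamp("2018-04-01")},  # gap
        ])
        assert len(apply_cohort_filters(visits, children)) == 1
        kept = apply_cohort_filters(visits, children, keep_between_windows=True)
        assert len(kept) == 2  # gap visit survives for outcome analyses

    def test_enrollment_exactly_at_window_edges(self):
        children = mk_children([
            {"child_id": "edge", "birth_date": pd.Timestamp("2018-07-25"),
             "enrollment_date": pd.Timestamp("2018-08-01")}])  # post enrollee
        visits = mk_visits([{"child_id": "edge", "visit_date": POST_DATE}])
        assert len(apply_cohort_filters(visits, children)) == 1


class TestCompleteness:
    def test_printed_count_reproduction(self):
        """850 of 912 recorded rounds to 93%."""
        children = mk_children([{"child_id": f"c{i}",
                                 "birth_date": pd.Timestamp("2018-08-15"),
                                 "enrollment_date": pd.Timestamp("2018-08-22")}
                                for i in range(912)])
        visits = mk_visits([
            {"child_id": f"c{i}", "visit_date": POST_DATE,
             "nurse_wfa": "normal" if i < 850 else None}
            for i in range(912)])
        rep = completeness(visits, children)
        row = rep[(rep["arm"] == "intervention") & (rep["period"] == "post")
                  & (rep["metric"] == "wfa")].iloc[0]
        assert (row["numerator"], row["denominator"], row["percent"]) == (850, 912, 93)

    def test_not_applicable_counts_as_complete(self):
        children = mk_children([{"child_id": f"c{i}",
                                 "birth_date": pd.Timestamp("2018-08-15"),
                                 "enrollment_date": pd.Timestamp("2018-08-22")}
                                for i in range(3)])
        visits = mk_visits([
            {"child_id": "c0", "visit_date": POST_DATE, "nurse_lhfa": "not_applicable"},
            {"child_id": "c1", "visit_date": POST_DATE, "nurse_lhfa": "not_applicable"},
            {"child_id": "c2", "visit_date": POST_DATE, "nurse_lhfa": None},
        ])
        rep = completeness(visits, children)
        row = rep[(rep["period"] == "post") & (rep["metric"] == "lhfa")
                  & (rep["arm"] == "intervention")].iloc[0]
        assert (row["numerator"], row["denominator"], row["percent"]) == (2, 3, 67)

    def test_corrected_age_denominator_is_preterm_visits_only(self):
        children = mk_children([
            {"child_id": "term", "gestational_age_weeks": 39.0,
             "birth_date": pd.Timestamp("2018-08-15"),
             "enrollment_date": pd.Timestamp("2018-08-22")},
            {"child_id": "pt", "gestational_age_weeks": 33.0,
             "birth_date": pd.Timestamp("2018-08-15"),
             "enrollment_date": pd.Timestamp("2018-08-22")},
            {"child_id": "ref_pt", "gestational_age_weeks": None,
             "referred_as_preterm": 1,
             "birth_date": pd.Timestamp("2018-08-15"),
             "enrollment_date": pd.Timestamp("2018-08-22")},
        ])
        visits = mk_visits([
            {"child_id": "term", "visit_date": POST_DATE,
             "nurse_corrected_age_recorded": 1},
            {"child_id": "pt", "visit_date": POST_DATE,
             "nurse_corrected_age_recorded": 1},
            {"child_id": "ref_pt", "visit_date": POST_DATE,
             "nurse_corrected_age_recorded": 0},
        ])
        rep = completeness(visits, children)
        row = rep[(rep["period"] == "post") & (rep["metric"] == "corrected_age")
                  & (rep["arm"] == "intervention")].iloc[0]
        assert (row["numerator"], row["denominator"], row["percent"]) == (1, 2, 50)

    def test_continuous_interval_entries_are_complete(self):
        children = mk_children([{"child_id": "c0",
                                 "birth_date": pd.Timestamp("2018-08-15"),
                                 "enrollment_date": pd.Timestamp("2018-08-22")}])
        visits = mk_visits([{"child_id": "c0", "visit_date": POST_DATE,
                             "nurse_interval_growth": 10.0}])
        rep = completeness(visits, children)
        row = rep[(rep["period"] == "post") & (rep["metric"] == "interval_growth")
                  & (rep["arm"] == "intervention")].iloc[0]
        assert row["percent"] == 100

    def test_empty_group_reports_missing_percent(self):
        children = mk_children([{"child_id": "c0",
                                 "birth_date": pd.Timestamp("2018-08-15"),
                                 "enrollment_date": pd.Timestamp("2018-08-22")}])
        visits = mk_visits([{"child_id": "c0", "visit_date": POST_DATE}])
        rep = completeness(visits, children)
        empty = rep[(rep["arm"] == "control") & (rep["metric"] == "weight")]
        assert (empty["denominator"] == 0).all()
        assert empty["percent"].isna().all()


class TestConcordance:
    def _setup(self, refs, visit_rows, child_rows=None):
        if child_rows is None:
            child_rows = [{"child_id": "c0",
                           "birth_date": pd.Timestamp("2018-06-01"),
                           "enrollment_date": pd.Timestamp("2018-06-08")}]
        children = mk_children(child_rows)
        visits = mk_visits(visit_rows)
        visits = apply_cohort_filters(visits, children)
        assessments = assess_cohort(children, visits, refs)
        return children, visits, assessments

    def test_matching_moderate_classification(self, refs):
        age = (POST_DATE - pd.Timestamp("2018-06-01")).days
        children, visits, a = self._setup(refs, [{
            "child_id": "c0", "visit_date": POST_DATE,
            "weight_g": 5000, "length_cm": length_at_z(refs, -2.4, age),
            "nurse_lhfa": "moderate"}])
        rep = concordance(visits, children, a)
        row = rep[(rep["metric"] == "lhfa") & (rep["period"] == "post")
                  & (rep["arm"] == "intervention")].iloc[0]
        assert (row["matching"], row["not_matching"]) == (1, 0)

    def test_insufficient_data_is_discordant(self, refs):
        children, visits, a = self._setup(refs, [{
            "child_id": "c0", "visit_date": POST_DATE,
            "weight_g": 5000, "length_cm": None, "nurse_lhfa": "normal"}])
        rep = concordance(visits, children, a)
        row = rep[(rep["metric"] == "lhfa") & (rep["period"] == "post")
                  & (rep["arm"] == "intervention")].iloc[0]
        assert (row["matching"], row["not_matching"]) == (0, 1)

    def test_implausible_measurement_is_discordant_even_if_category_agrees(self, refs):
        age = (POST_DATE - pd.Timestamp("2018-06-01")).days
        w = weight_at_z(refs, 6.5, age)   # fabricated entry
        children, visits, a = self._setup(refs, [{
            "child_id": "c0", "visit_date": POST_DATE,
            "weight_g": w, "length_cm": 62.0, "nurse_wfa": "normal"}])
        rep = concordance(visits, children, a)
        row = rep[(rep["metric"] == "wfa") & (rep["period"] == "post")
                  & (rep["arm"] == "intervention")].iloc[0]
        assert (row["matching"], row["not_matching"]) == (0, 1)

    def test_nurse_not_applicable_matches_only_true_na(self, refs):
        age = (POST_DATE - pd.Timestamp("2018-06-01")).days
        children, visits, a = self._setup(refs, [
            {"child_id": "c0", "visit_date": POST_DATE,
             "weight_g": 3000, "length_cm": 44.0, "nurse_wflh": "not_applicable"},
            {"child_id": "c0", "visit_date": POST_DATE + pd.Timedelta(days=14),
             "weight_g": 5000, "length_cm": 58.0, "nurse_wflh": "not_applicable"},
        ])
        rep = concordance(visits, children, a)
        row = rep[(rep["metric"] == "wflh") & (rep["period"] == "post")
                  & (rep["arm"] == "intervention")].iloc[0]
        # first visit: length below the 45 cm chart limit is a genuine NA
        # -> matching; second: classifiable -> nurse NA discordant
        assert (row["matching"], row["not_matching"]) == (1, 1)

    def test_continuous_interval_entry_enabling_correct_call_matches(self, refs):
        # corrected age ~2.4 months: threshold 20 g/day; gold rate 18 g/day,
        # so an uncategorised "18" enables the correct "inadequate" call
        d0 = pd.Timestamp("2018-09-01")
        d1 = d0 + pd.Timedelta(days=10)
        children, visits, a = self._setup(refs, [
            {"child_id": "c0", "visit_date": d0, "weight_g": 5000,
             "length_cm": 58.0},
            {"child_id": "c0", "visit_date": d1, "weight_g": 5180,
             "length_cm": 58.5, "nurse_interval_growth": 18.0},
        ], child_rows=[{"child_id": "c0",
                        "birth_date": pd.Timestamp("2018-07-01"),
                        "enrollment_date": pd.Timestamp("2018-07-08")}])
        rep = concordance(visits, children, a)
        row = rep[(rep["metric"] == "interval_growth") & (rep["period"] == "post")
                  & (rep["arm"] == "intervention")].iloc[0]
        assert (row["matching"], row["not_matching"]) == (1, 0)

    def test_continuous_entry_on_wrong_side_is_discordant(self, refs):
        # gold rate 18 g/day is inadequate below the 20 g/day band, but the
        # nurse's "25" would imply adequate
        d0 = pd.Timestamp("2018-09-01")
        d1 = d0 + pd.Timedelta(days=10)
        children, visits, a = self._setup(refs, [
            {"child_id": "c0", "visit_date": d0, "weight_g": 5000,
             "length_cm": 58.0},
            {"child_id": "c0", "visit_date": d1, "weight_g": 5180,
             "length_cm": 58.5, "nurse_interval_growth": 25.0},
        ], child_rows=[{"child_id": "c0",
                        "birth_date": pd.Timestamp("2018-07-01"),
                        "enrollment_date": pd.Timestamp("2018-07-08")}])
        rep = concordance(visits, children, a)
        row = rep[(rep["metric"] == "interval_growth") & (rep["period"] == "post")
                  & (rep["arm"] == "intervention")].iloc[0]
        assert (row["matching"], row["not_matching"]) == (0, 1)

    def test_first_visit_excluded_from_interval_only(self, refs):
        d0 = pd.Timestamp("2018-09-01")
        children, visits, a = self._setup(refs, [
            {"child_id": "c0", "visit_date": d0, "weight_g": 5000,
             "length_cm": 58.0, "nurse_interval_growth": "adequate",
             "nurse_wfa": "normal"},
        ])
        rep = concordance(visits, children, a)
        ig = rep[(rep["metric"] == "interval_growth") & (rep["period"] == "post")
                 & (rep["arm"] == "intervention")].iloc[0]
        wfa = rep[(rep["metric"] == "wfa") & (rep["period"] == "post")
                  & (rep["arm"] == "intervention")].iloc[0]
        assert ig["matching"] + ig["not_matching"] == 0
        assert wfa["matching"] + wfa["not_matching"] == 1

    def test_tallies_partition_nurse_assessed_visits(self, refs, small_cohort):
        children, visits, _ = small_cohort
        fv = apply_cohort_filters(visits, children)
        a = assess_cohort(children, fv, refs)
        rep = concordance(fv, children, a)
        comp = completeness(fv, children)
        assert (rep["matching"] + rep["not_matching"] >= 0).all()
        # concordance denominators never exceed the completeness numerators
        for _, r in rep.iterrows():
            c = comp[(comp["arm"] == r["arm"]) & (comp["period"] == r["period"])
                     & (comp["metric"] == r["metric"])].iloc[0]
            assert r["matching"] + r["not_matching"] <= c["numerator"]

    def test_order_invariance(self, refs, small_cohort):
        children, visits, _ = small_cohort
        fv = apply_cohort_filters(visits, children)
        a = assess_cohort(children, fv, refs)
        base = concordance(fv, children, a)
        perm = fv.sample(frac=1.0, random_state=11)
        again = concordance(perm, children, a.loc[perm.index])
        pd.testing.assert_frame_equal(base, again)


@pytest.mark.parametrize("x,expected", [(92.5, 93), (92.49, 92), (0.5, 1), (67.0, 67)])
def test_round_half_up(x, expected):
    assert round_half_up(x) == expected
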