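"""Child-level nutritional status at target corrected ages (2 and 6 months).

For each eligible child (enrolled before 2 months corrected age) the visit
closest to the target corrected age, within +/- 1 month (30.4375 days), is
selected; stunting (L/HFA z < -2), wasting (WFL/H z < -2), underweight
(WFA z < -2) and inadequate interval growth are read off the gold-standard
assessment of that visit.  Children with no qualifying visit, or with
incomplete or implausible measurement data for a given indicator, are
missing for that indicator and drop out of its prevalence denominator.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .assessment import weeks_early_days
from .ingest import DEFAULT_WINDOWS, StudyWindows
from .records import EXPOSURE_GROUPS
from .reference import DAYS_PER_MONTH
from .audit import round_half_up

TARGET_AGES_MONTHS = (2, 6)
#: half-width of the qualifying window around the target corrected age
WINDOW_DAYS = DAYS_PER_MONTH

OUTCOME_NAMES = ("stunted", "wasted", "underweight", "inadequate_growth")

_CLASS_TO_FLAG = {"normal": False, "moderate": True, "severe": True}
_INTERVAL_TO_FLAG = {"adequate": False, "inadequate": True}


def select_target_visit(child_visits: pd.DataFrame,
                        target_age_months: float) -> Optional[object]:
    """Index label of the visit closest to the target corrected age.

    ``child_visits`` needs a ``corrected_age_days`` column and, for the
    tie-break, a ``visit_date`` column.  Returns None when no visit falls
    within +/- 1 month of the target.  Ties between equidistant visits go to
    the earlier visit date; the selection is invariant to row order.
    """
    target_days = target_age_months * DAYS_PER_MONTH
    ca = pd.to_numeric(child_visits["corrected_age_days"], errors="coerce")
    dist = (ca - target_days).abs()
    ok = dist <= WINDOW_DAYS
    if not ok.any():
        return None
    cand = child_visits[ok].assign(_dist=dist[ok])
    cand = cand.sort_values(["_dist", "visit_date"], kind="mergesort")
    return cand.index[0]


def _flag(cls: object, implausible: object, mapping: dict) -> Optional[bool]:
    if pd.notna(implausible) and bool(implausible):
        return None
    if not isinstance(cls, str):
        return None
    return mapping.get(cls)  # not_applicable -> None


def child_outcomes(children: pd.DataFrame, visits: pd.DataFrame,
                   assessments: pd.DataFrame, target_age_months: float,
                   windows: StudyWindows = DEFAULT_WINDOWS) -> pd.DataFrame:
    """One row per eligible child: outcome flags at the target age.

    ``visits``/``assessments`` should already be cohort-filtered (with
    between-window visits retained) and index-aligned.  The exposure group
    crosses the child's arm with the care regime they enrolled under:
    "pre" for enrollment up to the end of the pre window, "post" after it
    (rollout happens right after the pre window closes, so children
    enrolling between the windows are followed under the new regime and
    reach their target ages during the post window).  Contamination
    filtering upstream removes pre-enrollees' post-window visits.
    """
    ch = children.copy()
    ch["child_id"] = ch["child_id"].astype(str)
    ga = pd.to_numeric(ch["gestational_age_weeks"], errors="coerce")
    enrol_age = (pd.to_datetime(ch["enrollment_date"])
                 - pd.to_datetime(ch["birth_date"])).dt.days.astype(float)
    early = ga.map(lambda g: weeks_early_days(g) if pd.notna(g) and g < 37 else 0)
    enrol_ca = enrol_age - early
    eligible = enrol_ca < 2 * DAYS_PER_MONTH

    vis = visits.copy()
    vis["child_id"] = vis["child_id"].astype(str)
    joined = vis.join(assessments[["corrected_age_days", "class_lhfa", "class_wflh",
                                   "class_wfa", "class_interval", "implausible_lhfa",
                                   "implausible_wflh", "implausible_wfa"]])

    rows = []
    for _, crow in ch[eligible].iterrows():
        cid = crow["child_id"]
        if pd.isna(crow["enrollment_date"]):
            continue
        enrol = pd.Timestamp(crow["enrollment_date"]).date()
        period = "pre" if enrol <= windows.pre_end else "post"
        cv = joined[joined["child_id"] == cid]
        sel = select_target_visit(cv, target_age_months) if len(cv) else None
        row = {
            "child_id": cid, "target_age_months": target_age_months,
            "arm": crow["arm"], "period": period,
            "facility_id": crow["facility_id"],
            "facility_type": crow["facility_type"],
            "selected_visit_date": None,
            "stunted": None, "wasted": None, "underweight": None,
            "inadequate_growth": None,
        }
        if sel is not None:
            v = cv.loc[sel]
            row["selected_visit_date"] = v["visit_date"]
            row["stunted"] = _flag(v["class_lhfa"], v["implausible_lhfa"], _CLASS_TO_FLAG)
            row["wasted"] = _flag(v["class_wflh"], v["implausible_wflh"], _CLASS_TO_FLAG)
            row["underweight"] = _flag(v["class_wfa"], v["implausible_wfa"], _CLASS_TO_FLAG)
            row["inadequate_growth"] = _flag(v["class_interval"], False, _INTERVAL_TO_FLAG)
        rows.append(row)
    return pd.DataFrame(rows)


def outcome_prevalence(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Per-group prevalence of each outcome among children with defined flags.

    Long frame: arm, period, target_age_months, outcome, numerator,
    denominator, percent (half-up integer; missing when denominator is 0).
    """
    rows = []
    for target in sorted(outcomes["target_age_months"].unique()):
        sub = outcomes[outcomes["target_age_months"] == target]
        for arm, period in EXPOSURE_GROUPS:
            g = sub[(sub["arm"] == arm) & (sub["period"] == period)]
            for name in OUTCOME_NAMES:
                defined = g[name].map(lambda v: isinstance(v, bool))
                den = int(defined.sum())
                num = int(g.loc[defined, name].map(bool).sum())
                rows.append({
                    "arm": arm, "period": period, "target_age_months": target,
                    "outcome": name, "numerator": num, "denominator": den,
                    "percent": round_half_up(100.0 * num / den) if den else None,
                })
    return pd.DataFrame(rows)
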