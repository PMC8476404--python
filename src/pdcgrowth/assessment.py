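"""Clinical core: corrected age, gold-standard z-scores, interval growth and
the rule-based nutritional classification with colour coding.

The decision layer reproduces a paediatric-development-clinic protocol for
high-risk (preterm / low-birthweight) infants:

* all growth indicators are evaluated at the *corrected* age — chronological
  age minus the days born before 40 weeks gestation — for preterm infants;
* length/height-for-age (L/HFA), weight-for-length/height (WFL/H) and
  weight-for-age (WFA) z-scores classify as normal (z >= -2), moderate
  (-3 <= z < -2) or severe (z < -3) malnutrition, with chart-limit
  "not applicable" conditions checked first;
* interval growth (average g/day since the last weighed visit) is judged
  adequate against age-banded thresholds from 20 g/day under 3 months down
  to 4 g/day at 16-24 months;
* classifications map to a traffic-light colour (green / yellow / red).

A gold-standard assessment recomputes all of this from the raw recorded
measurements, flagging implausible entries (|raw z| > 5).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .errors import DomainError, RecordError
from .records import Child, Visit, COLOURS
from .reference import (DAYS_PER_MONTH, WEIGHT_BASED, ReferenceSet,
                        interpolate_lms, zscore)

log = logging.getLogger(__name__)

GA_TERM_WEEKS = 37.0
LBW_CUTOFF_G = 2500.0
IMPLAUSIBLE_Z = 5.0

# (lower month, upper month, adequacy threshold g/day); bands partition [0, 24)
INTERVAL_BANDS = (
    (0.0, 3.0, 20.0),
    (3.0, 6.0, 15.0),
    (6.0, 8.0, 10.0),
    (8.0, 12.0, 6.0),
    (12.0, 16.0, 5.0),
    (16.0, 24.0, 4.0),
)

# chart-limit "not applicable" triggers per indicator
LHFA_MIN_LENGTH_CM = 42.0
WFLH_MIN_LENGTH_CM = 45.0
WFLH_MIN_WEIGHT_G = 1600.0   # 1.6 kg
WFA_MIN_WEIGHT_G = 1400.0    # 1.4 kg


class CorrectedAge(NamedTuple):
    days: int
    #: True when the child is preterm by referral but gestational age is
    #: undocumented, so chronological age was used unadjusted
    correction_unavailable: bool


def is_preterm(child: Child) -> bool:
    """Preterm: documented gestational age < 37 weeks, or referred as preterm
    with gestational age missing."""
    g = child.gestational_age_weeks
    if g is not None:
        return g < GA_TERM_WEEKS
    return bool(child.referred_as_preterm)


def is_lbw(child: Child) -> Optional[bool]:
    """Low birthweight: birthweight < 2500 g; None when birthweight missing."""
    if child.birthweight_g is None:
        return None
    return child.birthweight_g < LBW_CUTOFF_G


class BirthweightPercentiles:
    """10th-percentile birthweight lookup by sex and gestational age.

    Thin interpolating wrapper over a user-supplied table (e.g. an
    INTERGROWTH-21st extract) with columns sex, ga_weeks, p10_g.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        need = {"sex", "ga_weeks", "p10_g"}
        if not need.issubset(frame.columns):
            raise RecordError(f"percentile table needs columns {sorted(need)}")
        self._by_sex = {
            sx: g.sort_values("ga_weeks")[["ga_weeks", "p10_g"]].to_numpy(float)
            for sx, g in frame.groupby("sex")
        }

    def p10(self, sex: str, ga_weeks: float) -> float:
        arr = self._by_sex[sex]
        return float(np.interp(ga_weeks, arr[:, 0], arr[:, 1]))

    @classmethod
    def from_csv(cls, path) -> "BirthweightPercentiles":
        return cls(pd.read_csv(path))


def is_sga(child: Child, percentiles: BirthweightPercentiles) -> Optional[bool]:
    """Small-for-gestational-age: birthweight below the 10th percentile for
    gestational age and sex; None when either input is missing."""
    if child.gestational_age_weeks is None or child.birthweight_g is None:
        return None
    return child.birthweight_g < percentiles.p10(child.sex, child.gestational_age_weeks)


def weeks_early_days(gestational_age_weeks: float) -> int:
    """Days born early: round(7 * (40 - GA)); 0 for term births."""
    if gestational_age_weeks >= 40.0:
        return 0
    return int(round(7.0 * (40.0 - gestational_age_weeks)))


def corrected_age(child: Child, visit_date: dt.date) -> CorrectedAge:
    """Corrected age in days at ``visit_date`` (may be negative).

    Term children (GA >= 37 weeks, or not preterm) keep chronological age.
    Preterm children with documented gestational age subtract the days born
    early.  Preterm-by-referral children with missing gestational age fall
    back to chronological age with ``correction_unavailable`` set.
    """
    if visit_date < child.birth_date:
        raise DomainError(f"{child.child_id}: visit predates birth")
    chron = (visit_date - child.birth_date).days
    g = child.gestational_age_weeks
    if g is not None and g < GA_TERM_WEEKS:
        return CorrectedAge(chron - weeks_early_days(g), False)
    if g is None and child.referred_as_preterm:
        return CorrectedAge(chron, True)
    return CorrectedAge(chron, False)


def interval_growth(weight_now_g: Optional[float], weight_prev_g: Optional[float],
                    days_between: int) -> Optional[float]:
    """Average daily weight change, signed, in g/day; None when a weight is missing."""
    if weight_now_g is None or weight_prev_g is None:
        return None
    if days_between < 1:
        raise DomainError(f"days_between must be >= 1, got {days_between}")
    return (weight_now_g - weight_prev_g) / days_between


def interval_threshold(corrected_age_days: float) -> Optional[float]:
    """Adequacy threshold (g/day) for a corrected age inside [0, 24) months."""
    months = corrected_age_days / DAYS_PER_MONTH
    for lo, hi, thr in INTERVAL_BANDS:
        if lo <= months < hi:
            return thr
    return None


def classify_zscore(indicator: str, z: Optional[float], corrected_age_days: float,
                    weight_g: Optional[float], length_cm: Optional[float]) -> Optional[str]:
    """Table-rule classification for one z-score indicator.

    Not-applicable (chart-limit) conditions are checked before the z value;
    returns None when no rule fires and z could not be computed (insufficient
    data).  Boundaries are closed below: z = -2 is normal, z = -3 moderate.
    """
    if corrected_age_days < 0:
        return "not_applicable"
    if indicator == "length_for_age":
        if length_cm is not None and length_cm < LHFA_MIN_LENGTH_CM:
            return "not_applicable"
    elif indicator == "weight_for_length":
        if length_cm is not None and length_cm < WFLH_MIN_LENGTH_CM:
            return "not_applicable"
        if weight_g is not None and weight_g < WFLH_MIN_WEIGHT_G:
            return "not_applicable"
    elif indicator == "weight_for_age":
        if weight_g is not None and weight_g < WFA_MIN_WEIGHT_G:
            return "not_applicable"
    else:
        raise DomainError(f"unknown indicator {indicator!r}")
    if z is None:
        return None
    if z >= -2.0:
        return "normal"
    if z >= -3.0:
        return "moderate"
    return "severe"


def classify_interval_growth(rate_g_per_day: Optional[float], corrected_age_days: float,
                             prev_weight_present: bool) -> Optional[str]:
    """Adequate / inadequate / not_applicable for an interval-growth rate.

    Not applicable when the prior weight is missing or the corrected age lies
    outside [0, 24) months (bands are undefined there).
    """
    if corrected_age_days < 0 or corrected_age_days >= 24.0 * DAYS_PER_MONTH:
        return "not_applicable"
    if not prev_weight_present:
        return "not_applicable"
    if rate_g_per_day is None:
        return None
    thr = interval_threshold(corrected_age_days)
    return "adequate" if rate_g_per_day >= thr else "inadequate"


def colour_of(cls: Optional[str]) -> Optional[str]:
    """Traffic-light colour for a classification; None for NA / unclassified."""
    if cls is None:
        return None
    return COLOURS.get(cls)


@dataclass
class GrowthAssessment:
    """Gold-standard assessment of one visit."""

    chronological_age_days: int
    corrected_age_days: int
    correction_unavailable: bool = False
    z_lhfa: Optional[float] = None
    z_wflh: Optional[float] = None
    z_wfa: Optional[float] = None
    #: raw (unrestricted) z-scores, used for implausibility screening
    z_lhfa_raw: Optional[float] = None
    z_wflh_raw: Optional[float] = None
    z_wfa_raw: Optional[float] = None
    interval_growth_g_per_day: Optional[float] = None
    prev_weight_present: bool = False
    class_lhfa: Optional[str] = None
    class_wflh: Optional[str] = None
    class_wfa: Optional[str] = None
    class_interval: Optional[str] = None
    colour_lhfa: Optional[str] = field(default=None)
    colour_wflh: Optional[str] = field(default=None)
    colour_wfa: Optional[str] = field(default=None)
    colour_interval: Optional[str] = field(default=None)
    implausible_lhfa: bool = False
    implausible_wflh: bool = False
    implausible_wfa: bool = False
    implausible: bool = False


def _safe_z(references: ReferenceSet, indicator: str, sex: str,
            index_value: Optional[float], y_kg: Optional[float]) -> tuple[Optional[float], Optional[float]]:
    """(adjusted z, raw z) or (None, None) when inputs are missing/out of range."""
    if index_value is None or y_kg is None or y_kg <= 0:
        return None, None
    table = references.get(indicator, sex)
    if not table.contains(index_value):
        return None, None
    L, M, S = interpolate_lms(table, index_value)
    raw = zscore(y_kg, L, M, S, restricted=False)
    adj = zscore(y_kg, L, M, S, restricted=True) if indicator in WEIGHT_BASED else raw
    return adj, raw


def assess_visit(child: Child, visit: Visit, prev_visit: Optional[Visit],
                 references: ReferenceSet) -> GrowthAssessment:
    """Full gold-standard assessment of one visit.

    ``prev_visit`` must be the most recent earlier visit *with a recorded
    weight* (or None); interval growth uses it.  z-scores are left undefined
    when measurements are missing or the index is outside the reference span.
    """
    if child.sex not in ("male", "female"):
        raise RecordError(f"{child.child_id}: unknown sex {child.sex!r}")
    chron = (visit.visit_date - child.birth_date).days
    ca = corrected_age(child, visit.visit_date)
    weight_kg = visit.weight_g / 1000.0 if visit.weight_g is not None else None
    age_index = float(ca.days) if ca.days >= 0 else None

    z_lhfa, z_lhfa_raw = _safe_z(references, "length_for_age", child.sex,
                                 age_index, visit.length_cm)
    z_wfa, z_wfa_raw = _safe_z(references, "weight_for_age", child.sex,
                               age_index, weight_kg)
    z_wflh, z_wflh_raw = _safe_z(references, "weight_for_length", child.sex,
                                 visit.length_cm, weight_kg)

    prev_weight = prev_visit.weight_g if prev_visit is not None else None
    if prev_weight is not None:
        days_between = (visit.visit_date - prev_visit.visit_date).days
        rate = interval_growth(visit.weight_g, prev_weight, max(days_between, 1))
    else:
        rate = None

    a = GrowthAssessment(
        chronological_age_days=chron,
        corrected_age_days=ca.days,
        correction_unavailable=ca.correction_unavailable,
        z_lhfa=z_lhfa, z_wflh=z_wflh, z_wfa=z_wfa,
        z_lhfa_raw=z_lhfa_raw, z_wflh_raw=z_wflh_raw, z_wfa_raw=z_wfa_raw,
        interval_growth_g_per_day=rate,
        prev_weight_present=prev_weight is not None,
    )
    a.class_lhfa = classify_zscore("length_for_age", z_lhfa, ca.days,
                                   visit.weight_g, visit.length_cm)
    a.class_wflh = classify_zscore("weight_for_length", z_wflh, ca.days,
                                   visit.weight_g, visit.length_cm)
    a.class_wfa = classify_zscore("weight_for_age", z_wfa, ca.days,
                                  visit.weight_g, visit.length_cm)
    a.class_interval = classify_interval_growth(rate, ca.days, a.prev_weight_present)
    a.colour_lhfa = colour_of(a.class_lhfa)
    a.colour_wflh = colour_of(a.class_wflh)
    a.colour_wfa = colour_of(a.class_wfa)
    a.colour_interval = colour_of(a.class_interval)
    a.implausible_lhfa = z_lhfa_raw is not None and abs(z_lhfa_raw) > IMPLAUSIBLE_Z
    a.implausible_wflh = z_wflh_raw is not None and abs(z_wflh_raw) > IMPLAUSIBLE_Z
    a.implausible_wfa = z_wfa_raw is not None and abs(z_wfa_raw) > IMPLAUSIBLE_Z
    a.implausible = a.implausible_lhfa or a.implausible_wflh or a.implausible_wfa
    return a


_ASSESS_COLS = [
    "chronological_age_days", "corrected_age_days", "correction_unavailable",
    "z_lhfa", "z_wflh", "z_wfa", "z_lhfa_raw", "z_wflh_raw", "z_wfa_raw",
    "interval_growth_g_per_day", "prev_weight_present",
    "class_lhfa", "class_wflh", "class_wfa", "class_interval",
    "colour_lhfa", "colour_wflh", "colour_wfa", "colour_interval",
    "implausible_lhfa", "implausible_wflh", "implausible_wfa", "implausible",
]


def _child_from_row(row: pd.Series) -> Child:
    def _opt(v):
        return None if pd.isna(v) else float(v)
    return Child(
        child_id=str(row["child_id"]),
        birth_date=pd.Timestamp(row["birth_date"]).date(),
        sex=str(row["sex"]),
        enrollment_date=pd.Timestamp(row["enrollment_date"]).date(),
        facility_id=str(row["facility_id"]),
        facility_type=str(row["facility_type"]),
        arm=str(row["arm"]),
        gestational_age_weeks=_opt(row.get("gestational_age_weeks")),
        referred_as_preterm=bool(row.get("referred_as_preterm", False)),
        birthweight_g=_opt(row.get("birthweight_g")),
    )


def _visit_from_row(row: pd.Series) -> Visit:
    def _opt(v):
        return None if pd.isna(v) else float(v)
    # interval growth may arrive as a category string or a numeric rate
    nig = row.get("nurse_interval_growth")
    if isinstance(nig, str):
        nig = nig.strip() or None
        if nig is not None:
            try:
                nig = float(nig)
            except ValueError:
                pass
    elif nig is None or pd.isna(nig):
        nig = None
    else:
        nig = float(nig)

    def _cat(v):
        return v if (isinstance(v, str) and v != "") else None
    return Visit(
        child_id=str(row["child_id"]),
        visit_date=pd.Timestamp(row["visit_date"]).date(),
        visit_type=str(row.get("visit_type", "standard_growth")),
        weight_g=_opt(row.get("weight_g")),
        length_cm=_opt(row.get("length_cm")),
        nurse_corrected_age_recorded=bool(row.get("nurse_corrected_age_recorded", False)),
        nurse_lhfa=_cat(row.get("nurse_lhfa")),
        nurse_wflh=_cat(row.get("nurse_wflh")),
        nurse_wfa=_cat(row.get("nurse_wfa")),
        nurse_interval_growth=nig,
    )


def assess_cohort(children: pd.DataFrame, visits: pd.DataFrame,
                  references: ReferenceSet) -> pd.DataFrame:
    """Gold-standard assessment of every visit in a cohort.

    Returns a frame aligned to ``visits`` (same index) with one column per
    :class:`GrowthAssessment` field.  Visits of unknown children, or children
    failing record-level validation, are skipped with a log entry and carry
    all-missing assessment columns.

    Interval growth links each visit to the child's most recent *earlier*
    visit that has a recorded weight, regardless of intervening unweighed
    visits.
    """
    child_map: dict[str, Child] = {}
    for _, row in children.iterrows():
        try:
            c = _child_from_row(row)
        except (ValueError, KeyError) as exc:
            log.warning("skipping child record: %s", exc)
            continue
        child_map[c.child_id] = c

    out = pd.DataFrame(index=visits.index, columns=_ASSESS_COLS, dtype=object)
    order = visits.sort_values(["child_id", "visit_date"]).index
    last_weighed: dict[str, Visit] = {}
    for idx in order:
        row = visits.loc[idx]
        cid = str(row["child_id"])
        child = child_map.get(cid)
        if child is None:
            log.warning("visit %s: unknown child %s, skipped", idx, cid)
            continue
        visit = _visit_from_row(row)
        if visit.visit_date < child.birth_date:
            log.warning("visit %s: predates birth of %s, skipped", idx, cid)
            continue
        prev = last_weighed.get(cid)
        a = assess_visit(child, visit, prev, references)
        for col in _ASSESS_COLS:
            out.at[idx, col] = getattr(a, col)
        if visit.weight_g is not None:
            last_weighed[cid] = visit
    return out
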