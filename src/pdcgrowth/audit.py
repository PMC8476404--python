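"""Visit-level completeness and nurse-vs-gold-standard concordance audits.

Visits are cross-classified into four exposure groups (control/intervention
arm x pre/post period).  *Completeness* asks: did the nurse record the
assessment at all ("not applicable" counts as complete)?  *Concordance*
asks: among visits where the nurse recorded an assessment, does it agree
with the gold-standard classification recomputed from the raw measurements?

A nurse record is discordant when (1) the recorded category does not match
the recomputed one, (2) the raw data needed to validate it are missing or
out of reference range, or (3) for z-score metrics, the recorded
measurements are implausible (raw z beyond +/-5 SD).  Each child's first
visit is excluded from interval-growth concordance only, because no prior
weight exists in the record system for it.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .assessment import interval_threshold
from .ingest import DEFAULT_WINDOWS, StudyWindows
from .records import EXPOSURE_GROUPS, INTERVAL_CLASSES, Z_CLASSES

log = logging.getLogger(__name__)

COMPLETENESS_METRICS = ("weight", "length", "corrected_age", "lhfa", "wflh",
                        "wfa", "interval_growth")
CONCORDANCE_METRICS = ("lhfa", "wflh", "wfa", "interval_growth")

_Z_METRIC_CLASS = {"lhfa": "class_lhfa", "wflh": "class_wflh", "wfa": "class_wfa"}
_Z_METRIC_IMPL = {"lhfa": "implausible_lhfa", "wflh": "implausible_wflh",
                  "wfa": "implausible_wfa"}


def round_half_up(x: float) -> int:
    """Integer percent rounding with halves up (presentation convention)."""
    return int(math.floor(x + 0.5))


@dataclass
class AuditConfig:
    """Audit options.

    ``lhfa_standard_visits_only`` restricts the L/HFA metric (only) to
    standard growth-assessment visits on or after ``lhfa_cutover_date``,
    mirroring a recording-practice change; off by default because the
    cutover postdates the default study window.
    """

    lhfa_standard_visits_only: bool = False
    lhfa_cutover_date: dt.date = dt.date(2019, 3, 1)


def apply_cohort_filters(visits: pd.DataFrame, children: pd.DataFrame,
                         windows: StudyWindows = DEFAULT_WINDOWS,
                         keep_between_windows: bool = False) -> pd.DataFrame:
    """Restrict visits to the analysable cohort.

    Drops, with a log entry: orphan visits (no matching child record);
    visits dated outside the study calendar; and contaminated visits —
    post-period visits of children who enrolled in the pre period, whose
    treatment simply continued.

    The visit-level audits use the default (visits must fall inside one of
    the two exposure windows).  The child-level outcome analysis passes
    ``keep_between_windows=True``: the record system is continuous, so a
    pre-enrollee's follow-up visits between the windows still exist and may
    serve as target-age visits; only visits outside the overall extraction
    span are dropped.
    """
    known = set(children["child_id"].astype(str))
    vis = visits.copy()
    vis["child_id"] = vis["child_id"].astype(str)
    orphan = ~vis["child_id"].isin(known)
    if orphan.any():
        log.warning("dropping %d orphan visit(s) with no child record", orphan.sum())
    vis = vis[~orphan]

    if "period" not in vis.columns or vis["period"].isna().all():
        vis = vis.assign(period=vis["visit_date"].map(
            lambda d: windows.period_of(pd.Timestamp(d).date()) if pd.notna(d) else None))
    if keep_between_windows:
        dates = vis["visit_date"].map(lambda d: pd.Timestamp(d).date()
                                      if pd.notna(d) else None)
        out_of_window = dates.map(
            lambda d: d is None or d < windows.pre_start or d > windows.post_end)
    else:
        out_of_window = vis["period"].isna()
    if out_of_window.any():
        log.info("dropping %d visit(s) outside the study calendar", out_of_window.sum())
    vis = vis[~out_of_window]

    ch = children.copy()
    ch["child_id"] = ch["child_id"].astype(str)
    if "enrollment_period" in ch.columns:
        enrol = ch.set_index("child_id")["enrollment_period"]
    else:
        enrol = ch.set_index("child_id")["enrollment_date"].map(
            lambda d: windows.period_of(pd.Timestamp(d).date()) if pd.notna(d) else None)
    contaminated = (vis["period"] == "post") & (vis["child_id"].map(enrol) == "pre")
    if contaminated.any():
        log.info("dropping %d contaminated post-period visit(s) of pre-period "
                 "enrollees", contaminated.sum())
    return vis[~contaminated]


def _with_child_columns(visits: pd.DataFrame, children: pd.DataFrame,
                        windows: StudyWindows = DEFAULT_WINDOWS) -> pd.DataFrame:
    ch = children.copy()
    ch["child_id"] = ch["child_id"].astype(str)
    ga = pd.to_numeric(ch["gestational_age_weeks"], errors="coerce")
    referred = ch.get("referred_as_preterm", pd.Series(False, index=ch.index))
    ch["_preterm"] = (ga < 37.0) | (ga.isna() & referred.fillna(False).astype(bool))
    cols = ch.set_index("child_id")[["arm", "_preterm"]]
    vis = visits.copy()
    vis["child_id"] = vis["child_id"].astype(str)
    vis["arm"] = vis["child_id"].map(cols["arm"])
    vis["_preterm"] = vis["child_id"].map(cols["_preterm"]).astype(bool)
    if "period" not in vis.columns:
        vis["period"] = vis["visit_date"].map(
            lambda d: windows.period_of(pd.Timestamp(d).date()) if pd.notna(d) else None)
    return vis


def _recorded(series: pd.Series) -> pd.Series:
    """Non-empty entries count as recorded (category strings or numbers)."""
    def ok(v) -> bool:
        if isinstance(v, str):
            return v.strip() != ""
        return pd.notna(v)
    return series.map(ok)


def _lhfa_mask(vis: pd.DataFrame, config: AuditConfig) -> pd.Series:
    """Visit mask for the L/HFA metric under the visit-type restriction."""
    if not config.lhfa_standard_visits_only:
        return pd.Series(True, index=vis.index)
    dates = vis["visit_date"].map(lambda d: pd.Timestamp(d).date())
    before = dates < config.lhfa_cutover_date
    standard = vis.get("visit_type", pd.Series("standard_growth", index=vis.index))
    return before | (standard == "standard_growth")


def completeness(visits: pd.DataFrame, children: pd.DataFrame,
                 config: Optional[AuditConfig] = None) -> pd.DataFrame:
    """Per-group, per-metric recording completeness.

    Returns a long frame (arm, period, metric, numerator, denominator,
    percent); percent is half-up-rounded to an integer, missing when the
    denominator is zero.  The corrected-age denominator is preterm-child
    visits only; "not applicable" entries are complete; interval growth is
    complete whether recorded categorically or as a continuous rate.
    """
    config = config or AuditConfig()
    vis = _with_child_columns(visits, children)
    lhfa_ok = _lhfa_mask(vis, config)

    rows = []
    for arm, period in EXPOSURE_GROUPS:
        g = vis[(vis["arm"] == arm) & (vis["period"] == period)]
        for metric in COMPLETENESS_METRICS:
            if metric == "weight":
                den, num = g, g["weight_g"].notna()
            elif metric == "length":
                den, num = g, g["length_cm"].notna()
            elif metric == "corrected_age":
                den = g[g["_preterm"]]
                num = den["nurse_corrected_age_recorded"].fillna(False).astype(bool)
            elif metric == "interval_growth":
                den, num = g, _recorded(g["nurse_interval_growth"])
            elif metric == "lhfa":
                den = g[lhfa_ok.reindex(g.index, fill_value=True)]
                num = _recorded(den["nurse_lhfa"])
            else:
                den, num = g, _recorded(g[f"nurse_{metric}"])
            n_den = len(den)
            n_num = int(num.sum())
            rows.append({
                "arm": arm, "period": period, "metric": metric,
                "numerator": n_num, "denominator": n_den,
                "percent": round_half_up(100.0 * n_num / n_den) if n_den else None,
            })
    return pd.DataFrame(rows)


def _match_z_metric(nurse: object, gold: object, implausible: object) -> bool:
    if pd.notna(implausible) and bool(implausible):   # rule 3: implausible raw data
        return False
    if not isinstance(gold, str):               # rule 2: cannot validate
        return False
    return isinstance(nurse, str) and nurse == gold


def _match_interval(nurse: object, gold: object, corrected_age_days: object) -> bool:
    if not isinstance(gold, str):
        return False
    if isinstance(nurse, str) and nurse in INTERVAL_CLASSES:
        return nurse == gold
    # continuous entry: concordant iff it would classify the child correctly
    try:
        rate = float(nurse)
    except (TypeError, ValueError):
        return False
    if gold == "not_applicable":
        return False
    thr = interval_threshold(float(corrected_age_days))
    if thr is None:
        return False
    implied = "adequate" if rate >= thr else "inadequate"
    return implied == gold


def concordance(visits: pd.DataFrame, children: pd.DataFrame,
                assessments: pd.DataFrame,
                config: Optional[AuditConfig] = None) -> pd.DataFrame:
    """Per-group, per-metric agreement between nurse records and gold standard.

    ``assessments`` must be index-aligned with ``visits`` (see
    :func:`pdcgrowth.assessment.assess_cohort`).  Denominators are the visits
    where the nurse recorded that metric; each child's first visit is
    excluded from the interval-growth metric only.
    """
    config = config or AuditConfig()
    vis = _with_child_columns(visits, children)
    assess = assessments.reindex(vis.index)
    lhfa_ok = _lhfa_mask(vis, config)

    first_date = vis.groupby("child_id")["visit_date"].transform("min")
    not_first = vis["visit_date"] > first_date

    rows = []
    for arm, period in EXPOSURE_GROUPS:
        in_group = (vis["arm"] == arm) & (vis["period"] == period)
        for metric in CONCORDANCE_METRICS:
            if metric == "interval_growth":
                mask = in_group & not_first & _recorded(vis["nurse_interval_growth"])
                matches = [
                    _match_interval(vis.at[i, "nurse_interval_growth"],
                                    assess.at[i, "class_interval"],
                                    assess.at[i, "corrected_age_days"])
                    for i in vis.index[mask]
                ]
            else:
                mask = in_group & _recorded(vis[f"nurse_{metric}"])
                if metric == "lhfa":
                    mask &= lhfa_ok
                matches = [
                    _match_z_metric(vis.at[i, f"nurse_{metric}"],
                                    assess.at[i, _Z_METRIC_CLASS[metric]],
                                    assess.at[i, _Z_METRIC_IMPL[metric]])
                    for i in vis.index[mask]
                ]
            n = len(matches)
            m = int(sum(matches))
            rows.append({
                "arm": arm, "period": period, "metric": metric,
                "matching": m, "not_matching": n - m,
                "percent_matching": round_half_up(100.0 * m / n) if n else None,
            })
    return pd.DataFrame(rows)


def audit_wide(report: pd.DataFrame, value: str = "percent") -> pd.DataFrame:
    """Pivot a long audit report into a metric x exposure-group table."""
    wide = report.assign(group=report["arm"] + "_" + report["period"]).pivot(
        index="metric", columns="group", values=value)
    order = [f"{a}_{p}" for a, p in EXPOSURE_GROUPS]
    return wide[[c for c in order if c in wide.columns]]
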