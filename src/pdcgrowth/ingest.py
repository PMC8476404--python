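"""Ingest and validation of EMR extract tables, plus run configuration.

Column dictionary (CSV, UTF-8, header row required, empty field = missing,
dates ISO-8601, weights in grams):

``children.csv``
    child_id, birth_date, sex (male/female), gestational_age_weeks,
    referred_as_preterm (0/1), birthweight_g, enrollment_date, facility_id,
    facility_type (hospital/health_centre), arm (control/intervention)

``visits.csv``
    child_id, visit_date, visit_type (standard_growth/other), weight_g,
    length_cm, nurse_corrected_age_recorded (0/1), nurse_lhfa, nurse_wflh,
    nurse_wfa (normal/moderate/severe/not_applicable or empty),
    nurse_interval_growth (adequate/inadequate/not_applicable, a numeric
    g/day rate, or empty)

Validation flags — never silently drops — suspicious rows: out-of-range
gestational ages, non-positive measurements, date inversions, and (when
reference tables are supplied) measurements implying |raw z| > 5, which an
EMR audit would treat as data-entry errors to investigate.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .errors import SchemaError
from .assessment import IMPLAUSIBLE_Z, corrected_age, _child_from_row
from .reference import ReferenceSet, interpolate_lms, zscore

CHILD_REQUIRED = ["child_id", "birth_date", "sex", "enrollment_date",
                  "facility_id", "facility_type", "arm"]
CHILD_OPTIONAL = ["gestational_age_weeks", "referred_as_preterm", "birthweight_g"]
VISIT_REQUIRED = ["child_id", "visit_date"]
VISIT_OPTIONAL = ["visit_type", "weight_g", "length_cm",
                  "nurse_corrected_age_recorded", "nurse_lhfa", "nurse_wflh",
                  "nurse_wfa", "nurse_interval_growth"]


@dataclass(frozen=True)
class StudyWindows:
    """Calendar windows defining the pre and post exposure periods."""

    pre_start: dt.date
    pre_end: dt.date
    post_start: dt.date
    post_end: dt.date

    def period_of(self, date: dt.date) -> Optional[str]:
        if self.pre_start <= date <= self.pre_end:
            return "pre"
        if self.post_start <= date <= self.post_end:
            return "post"
        return None


#: the evaluation calendar: Aug 2017 - Jan 2018 pre, Aug 2018 - Jan 2019 post
DEFAULT_WINDOWS = StudyWindows(
    pre_start=dt.date(2017, 8, 1), pre_end=dt.date(2018, 1, 31),
    post_start=dt.date(2018, 8, 1), post_end=dt.date(2019, 1, 31),
)


@dataclass
class Issue:
    """One row-level validation finding."""

    table: str
    row: object          # index label in the source frame
    column: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.table}:{self.row}] {self.column}: {self.message}"


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


def _parse_dates(df: pd.DataFrame, cols: list[str], table: str,
                 issues: list[Issue]) -> None:
    for c in cols:
        parsed = pd.to_datetime(df[c], format="ISO8601", errors="coerce")
        for idx in df.index[parsed.isna() & df[c].notna()]:
            issues.append(Issue(table, idx, c, f"unparseable date {df.at[idx, c]!r}"))
        df[c] = parsed


def load_children(path: str | Path) -> tuple[pd.DataFrame, list[Issue]]:
    df = pd.read_csv(path)
    _require_columns(df, CHILD_REQUIRED, "children")
    issues: list[Issue] = []
    _parse_dates(df, ["birth_date", "enrollment_date"], "children", issues)
    for c in CHILD_OPTIONAL:
        if c not in df.columns:
            df[c] = pd.NA
    df["referred_as_preterm"] = df["referred_as_preterm"].fillna(0).astype(bool)

    ga = pd.to_numeric(df["gestational_age_weeks"], errors="coerce")
    bad_ga = ga.notna() & ~ga.between(20, 45, inclusive="neither")
    for idx in df.index[bad_ga]:
        issues.append(Issue("children", idx, "gestational_age_weeks",
                            f"outside (20, 45): {ga[idx]}"))
    df["gestational_age_weeks"] = ga.where(~bad_ga)

    bw = pd.to_numeric(df["birthweight_g"], errors="coerce")
    bad_bw = bw.notna() & (bw <= 0)
    for idx in df.index[bad_bw]:
        issues.append(Issue("children", idx, "birthweight_g",
                            f"non-positive: {bw[idx]}"))
    df["birthweight_g"] = bw.where(~bad_bw)

    inverted = df["enrollment_date"].notna() & df["birth_date"].notna() & (
        df["enrollment_date"] < df["birth_date"])
    for idx in df.index[inverted]:
        issues.append(Issue("children", idx, "enrollment_date", "precedes birth_date"))
    return df, issues


def load_visits(path: str | Path) -> tuple[pd.DataFrame, list[Issue]]:
    df = pd.read_csv(path)
    _require_columns(df, VISIT_REQUIRED, "visits")
    issues: list[Issue] = []
    _parse_dates(df, ["visit_date"], "visits", issues)
    for c in VISIT_OPTIONAL:
        if c not in df.columns:
            df[c] = pd.NA
    df["visit_type"] = df["visit_type"].fillna("standard_growth")
    df["nurse_corrected_age_recorded"] = (
        df["nurse_corrected_age_recorded"].fillna(0).astype(bool))
    for c in ("weight_g", "length_cm"):
        v = pd.to_numeric(df[c], errors="coerce")
        bad = v.notna() & (v <= 0)
        for idx in df.index[bad]:
            issues.append(Issue("visits", idx, c, f"non-positive: {v[idx]}"))
        df[c] = v.where(~bad)
    return df, issues


def load_and_validate(children_path: str | Path, visits_path: str | Path,
                      references: Optional[ReferenceSet] = None,
                      windows: StudyWindows = DEFAULT_WINDOWS,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, list[Issue]]:
    """Load both tables, cross-validate, derive periods, flag extreme values.

    Implausible measurements (|raw z| > 5 against the supplied references)
    are *flagged* in the issue log, never dropped: downstream concordance and
    outcome rules decide their fate.
    """
    children, issues = load_children(children_path)
    visits, vissues = load_visits(visits_path)
    issues.extend(vissues)

    birth = children.set_index("child_id")["birth_date"]
    vb = visits["child_id"].map(birth)
    orphan = vb.isna()
    for idx in visits.index[orphan]:
        issues.append(Issue("visits", idx, "child_id",
                            f"unknown child {visits.at[idx, 'child_id']!r}"))
    predates = visits["visit_date"].notna() & vb.notna() & (visits["visit_date"] < vb)
    for idx in visits.index[predates]:
        issues.append(Issue("visits", idx, "visit_date", "precedes child's birth date"))

    visits["period"] = visits["visit_date"].map(
        lambda d: windows.period_of(d.date()) if pd.notna(d) else None)
    children["enrollment_period"] = children["enrollment_date"].map(
        lambda d: windows.period_of(d.date()) if pd.notna(d) else None)

    if references is not None:
        issues.extend(flag_implausible(children, visits, references))
    return children, visits, issues


def flag_implausible(children: pd.DataFrame, visits: pd.DataFrame,
                     references: ReferenceSet) -> list[Issue]:
    """Flag measurements whose raw z-score lies beyond +/-5 SD."""
    issues: list[Issue] = []
    cmap = {}
    for _, row in children.iterrows():
        try:
            c = _child_from_row(row)
            cmap[c.child_id] = c
        except (ValueError, KeyError):
            continue
    for idx, row in visits.iterrows():
        child = cmap.get(str(row["child_id"]))
        if child is None or pd.isna(row["visit_date"]):
            continue
        vdate = pd.Timestamp(row["visit_date"]).date()
        if vdate < child.birth_date:
            continue
        ca = corrected_age(child, vdate).days
        checks = []
        if pd.notna(row.get("weight_g")) and ca >= 0:
            checks.append(("weight_g", "weight_for_age", float(ca),
                           float(row["weight_g"]) / 1000.0))
        if pd.notna(row.get("length_cm")) and ca >= 0:
            checks.append(("length_cm", "length_for_age", float(ca),
                           float(row["length_cm"])))
        for col, indicator, index_value, y in checks:
            table = references.get(indicator, child.sex)
            if not table.contains(index_value) or y <= 0:
                continue
            L, M, S = interpolate_lms(table, index_value)
            z = zscore(y, L, M, S, restricted=False)
            if abs(z) > IMPLAUSIBLE_Z:
                issues.append(Issue("visits", idx, col,
                                    f"implausible: raw {indicator} z = {z:.1f}"))
    return issues


@dataclass
class RunConfig:
    """Structured run configuration for the CLI pipeline."""

    children: str = "children.csv"
    visits: str = "visits.csv"
    references: dict = field(default_factory=dict)  # indicator -> path
    output_dir: str = "output"
    lhfa_standard_visits_only: bool = False
    lhfa_cutover_date: dt.date = dt.date(2019, 3, 1)
    did_adjust_facility_type: bool = False
    seed: int = 0
    windows: StudyWindows = DEFAULT_WINDOWS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("children", "visits", "references", "output_dir",
                    "lhfa_standard_visits_only", "did_adjust_facility_type", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "lhfa_cutover_date" in raw:
            kwargs["lhfa_cutover_date"] = pd.Timestamp(raw["lhfa_cutover_date"]).date()
        if "windows" in raw:
            w = {k: pd.Timestamp(v).date() for k, v in raw["windows"].items()}
            kwargs["windows"] = StudyWindows(**w)
        return cls(**kwargs)
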