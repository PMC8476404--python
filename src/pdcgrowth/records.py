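"""Child- and visit-level domain records and shared vocabulary.

The canonical on-disk form is a pair of delimited tables (see
:mod:`pdcgrowth.ingest` for the column dictionary); these dataclasses are the
row-level view the scalar clinical operations work on.  Weights are stored in
grams in files and records (as EMRs record them) and converted to kg inside
the reference layer.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

ARMS = ("control", "intervention")
PERIODS = ("pre", "post")
FACILITY_TYPES = ("hospital", "health_centre")
VISIT_TYPES = ("standard_growth", "other")

#: z-score classification categories (Table-style rule engine output)
Z_CLASSES = ("normal", "moderate", "severe", "not_applicable")
#: interval-growth classification categories
INTERVAL_CLASSES = ("adequate", "inadequate", "not_applicable")

#: the four arm x period exposure cells, in reporting order
EXPOSURE_GROUPS = (
    ("control", "pre"),
    ("control", "post"),
    ("intervention", "pre"),
    ("intervention", "post"),
)

COLOURS = {"normal": "green", "moderate": "yellow", "severe": "red",
           "adequate": "green", "inadequate": "red"}


@dataclass
class Child:
    """One enrolled child.  Gestational age and birthweight may be missing."""

    child_id: str
    birth_date: dt.date
    sex: str
    enrollment_date: dt.date
    facility_id: str
    facility_type: str
    arm: str
    gestational_age_weeks: Optional[float] = None
    referred_as_preterm: bool = False
    birthweight_g: Optional[float] = None

    def __post_init__(self) -> None:
        if self.enrollment_date < self.birth_date:
            raise ValueError(f"{self.child_id}: enrollment before birth")
        g = self.gestational_age_weeks
        if g is not None and not (20.0 < g < 45.0):
            raise ValueError(f"{self.child_id}: gestational age {g} outside (20, 45) weeks")


@dataclass
class Visit:
    """One clinic visit: raw measurements plus the nurse's recorded assessments.

    ``nurse_interval_growth`` is either a category string (``adequate`` /
    ``inadequate`` / ``not_applicable``), a continuous rate in g/day, or None
    when nothing was recorded.
    """

    child_id: str
    visit_date: dt.date
    visit_type: str = "standard_growth"
    weight_g: Optional[float] = None
    length_cm: Optional[float] = None
    nurse_corrected_age_recorded: bool = False
    nurse_lhfa: Optional[str] = None
    nurse_wflh: Optional[str] = None
    nurse_wfa: Optional[str] = None
    nurse_interval_growth: Optional[str | float] = None

    def __post_init__(self) -> None:
        if self.weight_g is not None and self.weight_g <= 0:
            raise ValueError(f"{self.child_id}: non-positive weight {self.weight_g}")
        if self.length_cm is not None and self.length_cm <= 0:
            raise ValueError(f"{self.child_id}: non-positive length {self.length_cm}")
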