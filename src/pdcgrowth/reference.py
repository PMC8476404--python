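"""LMS growth-reference machinery.

A growth standard parameterises the distribution of a measurement ``y``
(weight in kg, length/height in cm) at each value of an index (age in days,
or length in cm for weight-for-length) by three numbers: the Box-Cox power
``L``, the median ``M`` and the coefficient of variation ``S``.  The z-score
of a measurement is

    z = ((y / M)**L - 1) / (L * S)        for L != 0
    z = ln(y / M) / S                     for L == 0

Weight-based indicators conventionally receive a *restricted* adjustment
beyond |z| = 3: the score is extended linearly in measurement units between
the curves at 2 and 3 SD, i.e. for z > 3

    z* = 3 + (y - SD3) / (SD3 - SD2)

and mirrored below -3, where SDk is the measurement at z = k obtained from
:func:`inverse_zscore`.  Length-based indicators never use the adjustment.

Tables are plain delimited text (tab or comma), one row per index value,
columns ``sex | index | L | M | S`` with the sex column optional and coded
``1``/``2`` or ``m``/``f``.  Interpolation between adjacent rows is linear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, RangeError, SchemaError

INDICATORS = ("weight_for_age", "length_for_age", "weight_for_length")
#: indicators whose z-scores receive the restricted (SD2/SD3) adjustment
WEIGHT_BASED = ("weight_for_age", "weight_for_length")
SEXES = ("male", "female")

#: days per month used wherever month-valued ages or thresholds are converted
DAYS_PER_MONTH = 30.4375


def zscore(y: float, L: float, M: float, S: float, restricted: bool = False) -> float:
    """LMS z-score of measurement ``y`` given parameters (L, M, S).

    With ``restricted=True`` the value is linearly extended in measurement
    units beyond |z| = 3 (weight-indicator convention); otherwise the raw
    Box-Cox value is returned.
    """
    if not y > 0:
        raise DomainError(f"measurement must be positive, got {y!r}")
    if M <= 0 or S <= 0:
        raise DomainError(f"M and S must be positive, got M={M!r}, S={S!r}")
    if L == 0.0:
        z = math.log(y / M) / S
    else:
        z = ((y / M) ** L - 1.0) / (L * S)
    if not restricted or abs(z) <= 3.0:
        return z
    if z > 3.0:
        sd3 = inverse_zscore(3.0, L, M, S)
        sd2 = inverse_zscore(2.0, L, M, S)
        return 3.0 + (y - sd3) / (sd3 - sd2)
    sd3n = inverse_zscore(-3.0, L, M, S)
    sd2n = inverse_zscore(-2.0, L, M, S)
    return -3.0 + (y - sd3n) / (sd2n - sd3n)


def inverse_zscore(z: float, L: float, M: float, S: float) -> float:
    """Measurement at z-score ``z``: y = M (1 + L S z)^(1/L), or M e^(S z) at L=0."""
    if M <= 0 or S <= 0:
        raise DomainError(f"M and S must be positive, got M={M!r}, S={S!r}")
    if L == 0.0:
        return M * math.exp(S * z)
    base = 1.0 + L * S * z
    if base <= 0.0:
        raise DomainError(f"inverse z-score undefined: 1 + L*S*z = {base!r} <= 0")
    return M * base ** (1.0 / L)


@dataclass(frozen=True)
class LMSRecord:
    """One row of a reference table: (index_value, L, M, S)."""

    index_value: float
    L: float
    M: float
    S: float

    def __post_init__(self) -> None:
        if self.index_value < 0:
            raise DomainError(f"index_value must be non-negative, got {self.index_value}")
        if self.M <= 0 or self.S <= 0:
            raise DomainError(f"M and S must be positive, got M={self.M}, S={self.S}")


@dataclass
class ReferenceTable:
    """An ordered LMS table for one indicator and sex.

    Age-indexed indicators use days; weight-for-length is indexed by
    length/height in cm.
    """

    indicator: str
    sex: str
    records: list[LMSRecord] = field(repr=False)

    def __post_init__(self) -> None:
        if self.indicator not in INDICATORS:
            raise SchemaError(f"unknown indicator {self.indicator!r}")
        if self.sex not in SEXES:
            raise SchemaError(f"unknown sex {self.sex!r}")
        if not self.records:
            raise SchemaError("reference table must be non-empty")
        idx = np.array([r.index_value for r in self.records], dtype=float)
        if not np.all(np.diff(idx) > 0):
            raise SchemaError("index values must be strictly increasing")
        self._index = idx
        self._L = np.array([r.L for r in self.records], dtype=float)
        self._M = np.array([r.M for r in self.records], dtype=float)
        self._S = np.array([r.S for r in self.records], dtype=float)

    @property
    def index_kind(self) -> str:
        return "length_cm" if self.indicator == "weight_for_length" else "age_days"

    @property
    def span(self) -> tuple[float, float]:
        return float(self._index[0]), float(self._index[-1])

    def contains(self, index_value: float) -> bool:
        lo, hi = self.span
        return lo <= index_value <= hi

    def lms_at(self, index_value: float) -> tuple[float, float, float]:
        return interpolate_lms(self, index_value)


def interpolate_lms(table: ReferenceTable, index_value: float) -> tuple[float, float, float]:
    """(L, M, S) at ``index_value``, linearly interpolated between bracketing rows.

    Exact at knots.  Raises :class:`RangeError` outside the table's span.
    """
    lo, hi = table.span
    if not (lo <= index_value <= hi):
        raise RangeError(
            f"{table.indicator}/{table.sex}: index {index_value} outside table span [{lo}, {hi}]"
        )
    L = float(np.interp(index_value, table._index, table._L))
    M = float(np.interp(index_value, table._index, table._M))
    S = float(np.interp(index_value, table._index, table._S))
    return L, M, S


class ReferenceSet:
    """The collection of reference tables the assessment pipeline needs.

    Keyed by (indicator, sex); all six tables (three indicators, two sexes)
    must be present before assessment.
    """

    def __init__(self, tables: Iterable[ReferenceTable] = ()) -> None:
        self._tables: dict[tuple[str, str], ReferenceTable] = {}
        for t in tables:
            self.add(t)

    def add(self, table: ReferenceTable) -> None:
        self._tables[(table.indicator, table.sex)] = table

    def get(self, indicator: str, sex: str) -> ReferenceTable:
        try:
            return self._tables[(indicator, sex)]
        except KeyError:
            raise SchemaError(f"no reference table loaded for {indicator}/{sex}") from None

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._tables

    def zscore_of(self, indicator: str, sex: str, index_value: float, y: float,
                  restricted: bool | None = None) -> float:
        """Convenience: interpolate and score in one call.

        ``restricted=None`` applies the weight-indicator convention
        (adjustment for weight-for-age and weight-for-length only).
        """
        if restricted is None:
            restricted = indicator in WEIGHT_BASED
        L, M, S = interpolate_lms(self.get(indicator, sex), index_value)
        return zscore(y, L, M, S, restricted=restricted)

    @classmethod
    def from_files(cls, paths: Mapping[str, str | Path]) -> "ReferenceSet":
        """Load a set from ``{indicator: path}``; each file holds both sexes."""
        rs = cls()
        for indicator, path in paths.items():
            for table in load_lms_table(path, indicator).values():
                rs.add(table)
        return rs


_SEX_CODES = {"1": "male", "2": "female", "m": "male", "f": "female",
              "male": "male", "female": "female"}


def _normalise_sex(value: object) -> str:
    code = str(value).strip().lower()
    # floats like 1.0 survive round-tripping through pandas
    if code.endswith(".0"):
        code = code[:-2]
    try:
        return _SEX_CODES[code]
    except KeyError:
        raise SchemaError(f"unrecognised sex code {value!r}") from None


def load_lms_table(path: str | Path, indicator: str,
                   sex: str | None = None) -> dict[str, ReferenceTable]:
    """Read a delimited LMS file into per-sex :class:`ReferenceTable` objects.

    Accepts tab- or comma-delimited files with a header.  Columns named
    ``l``/``m``/``s`` (case-insensitive) hold the parameters; a column named
    ``sex`` (coded 1/2 or m/f) is optional — without it ``sex`` must be given.
    The remaining column is taken as the index (age in days or length in cm);
    the loader is agnostic to table granularity.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.strip().lower(): c for c in df.columns}
    for needed in ("l", "m", "s"):
        if needed not in cols:
            raise SchemaError(f"{path}: missing required column {needed!r}")
    sex_col = cols.get("sex")
    index_candidates = [c for c in df.columns
                        if c not in {cols["l"], cols["m"], cols["s"]} and c != sex_col]
    if not index_candidates:
        raise SchemaError(f"{path}: no index column found")
    index_col = index_candidates[0]

    out: dict[str, ReferenceTable] = {}
    if sex_col is not None:
        grouped = dict(iter(df.groupby(df[sex_col].map(_normalise_sex))))
    else:
        if sex is None:
            raise SchemaError(f"{path}: file has no sex column; pass sex= explicitly")
        grouped = {sex: df}

    for sx, g in grouped.items():
        g = g.sort_values(index_col)
        records = [
            LMSRecord(float(r[index_col]), float(r[cols["l"]]),
                      float(r[cols["m"]]), float(r[cols["s"]]))
            for _, r in g.iterrows()
        ]
        out[sx] = ReferenceTable(indicator=indicator, sex=sx, records=records)
    return out


def write_lms_table(tables: Iterable[ReferenceTable], path: str | Path,
                    sep: str = ",") -> None:
    """Write tables (any mix of sexes, one indicator) in the loader's dialect."""
    rows = []
    for t in tables:
        for r in t.records:
            rows.append({"sex": t.sex, "index": r.index_value,
                         "l": r.L, "m": r.M, "s": r.S})
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
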