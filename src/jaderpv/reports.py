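"""Spontaneous-report data model and four-table CSV dialect.

A JADER-style extract comes as four linked CSV tables sharing a case
identifier: DEMO (one row per case: sex, age, body weight), DRUG (drug
entries with a causality role and administration route), REAC (adverse
events coded as MedDRA preferred-term names, with onset date) and HIST
(medical-history preferred terms).  This module defines the in-memory
model (:class:`ReportCase` and its children), the partial-date type used
for onset arithmetic, and the readers/writers for the dialect.

Dialect conventions
-------------------
* dates are ISO text truncated to their resolution: ``"2020"``,
  ``"2020-03"``, ``"2020-03-15"``;
* age may be a plain integer (``"83"``), a decade band (``"70s"``), a
  qualitative token (``"elderly"``) or empty;
* weight may be a number (``"52"``), a 10-kg band (``"40s_kg"``) or empty;
* drug roles are ``suspected | concomitant | interacting``; sex is
  ``female | male | unknown``.
"""

from __future__ import annotations

import csv
import datetime as _dt
import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "DateResolution",
    "PartialDate",
    "DrugRole",
    "DrugEntry",
    "EventEntry",
    "HistoryEntry",
    "Demographics",
    "ReportCase",
    "LoadSummary",
    "SchemaError",
    "NON_NUMERIC_AGE",
    "parse_age",
    "parse_weight",
    "parse_partial_date",
    "resolve_partial_date",
    "read_tables",
    "write_tables",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class DateResolution(str, enum.Enum):
    YEAR = "year"
    YEAR_MONTH = "year_month"
    FULL = "full"


@dataclass(frozen=True, order=True)
class PartialDate:
    """A calendar date known to year, year-month, or full-day resolution."""

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day requires month")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            # validates day against month length / leap years
            _dt.date(self.year, self.month, self.day)

    @property
    def resolution(self) -> DateResolution:
        if self.day is not None:
            return DateResolution.FULL
        if self.month is not None:
            return DateResolution.YEAR_MONTH
        return DateResolution.YEAR

    def isoformat(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.isoformat()


class DrugRole(str, enum.Enum):
    SUSPECTED = "suspected"
    CONCOMITANT = "concomitant"
    INTERACTING = "interacting"


@dataclass(frozen=True)
class DrugEntry:
    case_id: str
    generic_name: str
    role: DrugRole
    route: str = ""
    start_date: PartialDate | None = None


@dataclass(frozen=True)
class EventEntry:
    case_id: str
    pt_name: str
    onset_date: PartialDate | None = None

    def __post_init__(self) -> None:
        if not self.pt_name:
            raise ValueError("pt_name must be non-empty")


@dataclass(frozen=True)
class HistoryEntry:
    case_id: str
    pt_name: str

    def __post_init__(self) -> None:
        if not self.pt_name:
            raise ValueError("pt_name must be non-empty")


class _NonNumericAge:
    """Sentinel for qualitative age tokens (pediatric/adult/elderly)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NON_NUMERIC_AGE"


NON_NUMERIC_AGE = _NonNumericAge()

_QUALITATIVE_AGE_TOKENS = frozenset(
    {"pediatric", "paediatric", "child", "infant", "neonate",
     "adult", "elderly", "older", "adolescent", "youth"}
)
_MISSING_TOKENS = frozenset({"", "unknown", "na", "n/a", "none", "missing"})


def parse_age(age_raw: str | None) -> int | None | _NonNumericAge:
    """Parse an age field to years, a missing value, or the non-numeric flag.

    Plain integers parse to themselves; decade-band tokens (``"70s"``)
    parse to the band's lower bound; qualitative tokens such as
    ``"elderly"`` return :data:`NON_NUMERIC_AGE`; empty/unknown returns
    ``None``.  Total: every input maps to exactly one of the three.
    """
    if age_raw is None:
        return None
    tok = age_raw.strip().lower()
    if tok in _MISSING_TOKENS:
        return None
    if tok in _QUALITATIVE_AGE_TOKENS:
        return NON_NUMERIC_AGE
    m = re.fullmatch(r"(\d+)s", tok)
    if m:
        return int(m.group(1))
    try:
        val = int(tok)
    except ValueError:
        return NON_NUMERIC_AGE
    return val if val >= 0 else NON_NUMERIC_AGE


def parse_weight(weight_raw: str | None) -> float | None:
    """Parse a weight field to kilograms or a missing value.

    Numeric strings parse to their value; 10-kg band tokens
    (``"40s_kg"``) map to the band lower bound; anything else is missing.
    """
    if weight_raw is None:
        return None
    tok = weight_raw.strip().lower()
    if tok in _MISSING_TOKENS:
        return None
    m = re.fullmatch(r"(\d+)s_kg", tok)
    if m:
        return float(m.group(1))
    try:
        val = float(tok)
    except ValueError:
        return None
    return val if val >= 0 else None


@dataclass(frozen=True)
class Demographics:
    case_id: str
    sex: str = "unknown"  # female | male | unknown
    age_raw: str = ""
    weight_raw: str = ""

    @property
    def age_years(self) -> int | None | _NonNumericAge:
        return parse_age(self.age_raw)

    @property
    def weight_kg(self) -> float | None:
        return parse_weight(self.weight_raw)


@dataclass
class ReportCase:
    """One spontaneous report: demographics plus child entries.

    Empty drug or event lists are legal at load time; such cases are
    excluded later by the cohort filter, not rejected here.
    """

    demographics: Demographics
    drugs: list[DrugEntry] = field(default_factory=list)
    events: list[EventEntry] = field(default_factory=list)
    histories: list[HistoryEntry] = field(default_factory=list)

    @property
    def case_id(self) -> str:
        return self.demographics.case_id

    def __post_init__(self) -> None:
        cid = self.demographics.case_id
        for child in (*self.drugs, *self.events, *self.histories):
            if child.case_id != cid:
                raise ValueError(
                    f"child case_id {child.case_id!r} != {cid!r}"
                )


# ---------------------------------------------------------------------------
# partial dates

_DATE_RE = re.compile(r"(\d{4})(?:-(\d{2})(?:-(\d{2}))?)?")


def parse_partial_date(text: str | None) -> PartialDate | None:
    """Parse ISO text truncated to resolution; empty/unknown -> None."""
    if text is None:
        return None
    tok = text.strip()
    if tok.lower() in _MISSING_TOKENS:
        return None
    m = _DATE_RE.fullmatch(tok)
    if m is None:
        raise ValueError(f"malformed date: {text!r}")
    y, mo, d = m.groups()
    return PartialDate(int(y), int(mo) if mo else None, int(d) if d else None)


class DateNotResolvable(ValueError):
    """Raised for year-only dates, which cannot enter onset arithmetic."""


def resolve_partial_date(d: PartialDate) -> _dt.date:
    """Resolve to a calendar day: full dates to themselves, year-month
    dates to day 1 of the month.  Year-only dates raise
    :class:`DateNotResolvable`."""
    if d.resolution is DateResolution.YEAR:
        raise DateNotResolvable(f"year-only date {d} cannot be resolved")
    return _dt.date(d.year, d.month, d.day if d.day is not None else 1)


# ---------------------------------------------------------------------------
# four-table I/O

DEMO_COLUMNS = ("case_id", "sex", "age", "weight")
DRUG_COLUMNS = ("case_id", "generic_name", "role", "route", "start_date")
REAC_COLUMNS = ("case_id", "pt_name", "onset_date")
HIST_COLUMNS = ("case_id", "pt_name")


@dataclass
class LoadSummary:
    """Bookkeeping from :func:`read_tables`.

    ``orphans`` holds child rows whose case_id has no DEMO row —
    spontaneous-report extracts are dirty, so these are reported rather
    than fatal.  ``row_errors`` holds ``(table, line_number, message)``
    for malformed rows that were skipped.
    """

    n_cases: int = 0
    orphans: list[tuple[str, str]] = field(default_factory=list)  # (table, case_id)
    row_errors: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.orphans and not self.row_errors


def _check_header(name: str, fieldnames: Sequence[str] | None,
                  required: Sequence[str]) -> None:
    have = set(fieldnames or ())
    for col in required:
        if col not in have:
            raise SchemaError(f"{name} table is missing column {col!r}")


def _iter_rows(path: Path, name: str, required: Sequence[str]):
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(name, reader.fieldnames, required)
        for row in reader:
            yield reader.line_num, row


def read_tables(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    hist_path: str | Path,
) -> tuple[list[ReportCase], LoadSummary]:
    """Read the four-table dialect into one :class:`ReportCase` per
    distinct DEMO case_id, joining child tables on case_id.

    Child rows referencing unknown case_ids become orphans in the
    returned :class:`LoadSummary`; malformed rows are skipped and
    reported there with their line number.
    """
    summary = LoadSummary()
    cases: dict[str, ReportCase] = {}

    for line, row in _iter_rows(Path(demo_path), "DEMO", DEMO_COLUMNS):
        cid = (row["case_id"] or "").strip()
        if not cid:
            summary.row_errors.append(("DEMO", line, "empty case_id"))
            continue
        sex = (row["sex"] or "unknown").strip().lower() or "unknown"
        if sex not in ("female", "male", "unknown"):
            summary.row_errors.append(("DEMO", line, f"bad sex token {sex!r}"))
            sex = "unknown"
        cases[cid] = ReportCase(
            Demographics(cid, sex, row["age"] or "", row["weight"] or "")
        )

    for line, row in _iter_rows(Path(drug_path), "DRUG", DRUG_COLUMNS):
        cid = (row["case_id"] or "").strip()
        try:
            entry = DrugEntry(
                cid,
                (row["generic_name"] or "").strip(),
                DrugRole((row["role"] or "").strip().lower()),
                (row["route"] or "").strip(),
                parse_partial_date(row["start_date"]),
            )
        except ValueError as exc:
            summary.row_errors.append(("DRUG", line, str(exc)))
            continue
        if cid in cases:
            cases[cid].drugs.append(entry)
        else:
            summary.orphans.append(("DRUG", cid))

    for line, row in _iter_rows(Path(reac_path), "REAC", REAC_COLUMNS):
        cid = (row["case_id"] or "").strip()
        try:
            entry = EventEntry(
                cid, (row["pt_name"] or "").strip(),
                parse_partial_date(row["onset_date"]),
            )
        except ValueError as exc:
            summary.row_errors.append(("REAC", line, str(exc)))
            continue
        if cid in cases:
            cases[cid].events.append(entry)
        else:
            summary.orphans.append(("REAC", cid))

    for line, row in _iter_rows(Path(hist_path), "HIST", HIST_COLUMNS):
        cid = (row["case_id"] or "").strip()
        try:
            entry = HistoryEntry(cid, (row["pt_name"] or "").strip())
        except ValueError as exc:
            summary.row_errors.append(("HIST", line, str(exc)))
            continue
        if cid in cases:
            cases[cid].histories.append(entry)
        else:
            summary.orphans.append(("HIST", cid))

    summary.n_cases = len(cases)
    return list(cases.values()), summary


def write_tables(
    cases: Iterable[ReportCase],
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    hist_path: str | Path,
) -> None:
    """Write cases back out in the four-table dialect (round-trips with
    :func:`read_tables`)."""

    cases = list(cases)

    def _fmt(d: PartialDate | None) -> str:
        return d.isoformat() if d is not None else ""

    with open(demo_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(DEMO_COLUMNS)
        for case in cases:
            dm = case.demographics
            w.writerow([dm.case_id, dm.sex, dm.age_raw, dm.weight_raw])

    with open(drug_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(DRUG_COLUMNS)
        for case in cases:
            for dr in case.drugs:
                w.writerow([dr.case_id, dr.generic_name, dr.role.value,
                            dr.route, _fmt(dr.start_date)])

    with open(reac_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(REAC_COLUMNS)
        for case in cases:
            for ev in case.events:
                w.writerow([ev.case_id, ev.pt_name, _fmt(ev.onset_date)])

    with open(hist_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(HIST_COLUMNS)
        for case in cases:
            for hs in case.histories:
                w.writerow([hs.case_id, hs.pt_name])
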