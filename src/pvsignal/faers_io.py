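"""Readers for FAERS-style quarterly ASCII tables and case-version deduplication.

The FDA Adverse Event Reporting System publishes quarterly ``$``-delimited
ASCII files (DEMO, DRUG, REAC, OUTC, INDI, THER), one header row per file.
Because every quarterly release re-publishes follow-up versions of earlier
cases, the same case identifier (``caseid``) typically appears under several
report-version identifiers (``primaryid``).  All statistics downstream assume
one row per case, so :func:`deduplicate` must run before anything else.

Dates in these files are bare digit strings with variable precision
(``YYYYMMDD``, ``YYYYMM`` or ``YYYY``); :func:`parse_date` keeps the precision
explicit instead of silently coercing to a day.
"""

from __future__ import annotations

import dataclasses
import datetime
import enum
import re
from typing import IO, Iterable, Iterator, Mapping, Sequence

__all__ = [
    "DatePrecision",
    "PartialDate",
    "DemoRecord",
    "DrugMention",
    "EventMention",
    "OutcomeRecord",
    "IndicationRecord",
    "TherRecord",
    "RowError",
    "ParseResult",
    "parse_date",
    "parse_table",
    "write_table",
    "deduplicate",
    "TABLE_COLUMNS",
    "VALID_ROLE_CODES",
]

VALID_ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

_WS = re.compile(r"\s+")


def _norm_ws(s: str) -> str:
    return _WS.sub(" ", s.strip())


class DatePrecision(enum.Enum):
    """Precision of a FAERS date field."""

    DAY = "day"
    MONTH = "month"
    YEAR = "year"
    ABSENT = "absent"


@dataclasses.dataclass(frozen=True)
class PartialDate:
    """A calendar date of explicit, possibly partial, precision.

    FAERS date columns carry 8, 6 or 4 digits; anything else (including
    impossible calendar dates) is treated as absent.  Partial dates are kept
    for year-level tabulation but are not usable for day arithmetic.
    """

    year: int | None
    month: int | None
    day: int | None
    precision: DatePrecision

    ABSENT: "PartialDate" = None  # type: ignore[assignment]  # set below

    @property
    def is_full(self) -> bool:
        return self.precision is DatePrecision.DAY

    @property
    def is_absent(self) -> bool:
        return self.precision is DatePrecision.ABSENT

    def to_date(self) -> datetime.date:
        if not self.is_full:
            raise ValueError(f"date {self.render()!r} is not day-precision")
        return datetime.date(self.year, self.month, self.day)

    def sort_key(self) -> int:
        """Monotone integer key: absent < year < year-month < full date."""
        y = self.year or 0
        m = self.month or 0
        d = self.day or 0
        return y * 10000 + m * 100 + d

    def render(self) -> str:
        """Back to the FAERS digit representation ('' when absent)."""
        if self.precision is DatePrecision.ABSENT:
            return ""
        if self.precision is DatePrecision.YEAR:
            return f"{self.year:04d}"
        if self.precision is DatePrecision.MONTH:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}{self.month:02d}{self.day:02d}"


PartialDate.ABSENT = PartialDate(None, None, None, DatePrecision.ABSENT)


def parse_date(raw: str | None) -> PartialDate:
    """Parse a FAERS digit-string date; total — bad input maps to absent.

    8 digits -> full date, 6 -> year-month, 4 -> year.  Calendar-invalid
    strings (month 13, day 32, ...) are absent, never an exception.
    """
    s = (raw or "").strip()
    if not s.isdigit():
        return PartialDate.ABSENT
    if len(s) == 8:
        y, m, d = int(s[:4]), int(s[4:6]), int(s[6:])
        try:
            datetime.date(y, m, d)
        except ValueError:
            return PartialDate.ABSENT
        return PartialDate(y, m, d, DatePrecision.DAY)
    if len(s) == 6:
        y, m = int(s[:4]), int(s[4:])
        if not 1 <= m <= 12 or y == 0:
            return PartialDate.ABSENT
        return PartialDate(y, m, None, DatePrecision.MONTH)
    if len(s) == 4:
        y = int(s)
        if y == 0:
            return PartialDate.ABSENT
        return PartialDate(y, None, None, DatePrecision.YEAR)
    return PartialDate.ABSENT


# --------------------------------------------------------------------------
# Typed records
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class DemoRecord:
    """One DEMO row: demographics and administrative dates of a report version."""

    primaryid: str
    caseid: str
    fda_dt: PartialDate = PartialDate.ABSENT
    event_dt: PartialDate = PartialDate.ABSENT
    age: float | None = None
    age_cod: str | None = None
    sex: str | None = None
    occp_cod: str | None = None
    occr_country: str | None = None
    extras: Mapping[str, str] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass(frozen=True)
class DrugMention:
    """One DRUG row: a drug named in a report with its reported role."""

    primaryid: str
    drug_seq: str
    drugname: str = ""
    prod_ai: str | None = None
    role_cod: str | None = None
    extras: Mapping[str, str] = dataclasses.field(default_factory=dict)

    @property
    def role_valid(self) -> bool:
        return self.role_cod in VALID_ROLE_CODES


@dataclasses.dataclass(frozen=True)
class EventMention:
    """One REAC row: a (report, MedDRA Preferred Term) pair."""

    primaryid: str
    pt: str
    extras: Mapping[str, str] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass(frozen=True)
class OutcomeRecord:
    """One OUTC row: a serious-outcome code (DE/LT/HO/DS/CA/RI/OT)."""

    primaryid: str
    outc_cod: str
    extras: Mapping[str, str] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass(frozen=True)
class IndicationRecord:
    """One INDI row: the coded indication of one drug of a report."""

    primaryid: str
    indi_drug_seq: str
    indi_pt: str
    extras: Mapping[str, str] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass(frozen=True)
class TherRecord:
    """One THER row: therapy dates of one drug of a report."""

    primaryid: str
    dsg_drug_seq: str
    start_dt: PartialDate = PartialDate.ABSENT
    extras: Mapping[str, str] = dataclasses.field(default_factory=dict)


#: Canonical columns per table kind (extra header columns are preserved
#: verbatim in ``extras``).
TABLE_COLUMNS: dict[str, tuple[str, ...]] = {
    "DEMO": (
        "primaryid",
        "caseid",
        "fda_dt",
        "event_dt",
        "age",
        "age_cod",
        "sex",
        "occp_cod",
        "occr_country",
    ),
    "DRUG": ("primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"),
    "REAC": ("primaryid", "pt"),
    "OUTC": ("primaryid", "outc_cod"),
    "INDI": ("primaryid", "indi_drug_seq", "indi_pt"),
    "THER": ("primaryid", "dsg_drug_seq", "start_dt"),
}

_RECORD_TYPES = {
    "DEMO": DemoRecord,
    "DRUG": DrugMention,
    "REAC": EventMention,
    "OUTC": OutcomeRecord,
    "INDI": IndicationRecord,
    "THER": TherRecord,
}


@dataclasses.dataclass(frozen=True)
class RowError:
    line_no: int
    reason: str


@dataclasses.dataclass
class ParseResult:
    """Records plus row-level accounting from one table parse."""

    kind: str
    records: list
    n_rows: int
    errors: list[RowError]

    def __iter__(self) -> Iterator:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_errors(self) -> int:
        return len(self.errors)

    def log(self) -> str:
        lines = [
            f"{self.kind}: {self.n_rows} data rows, "
            f"{len(self.records)} parsed, {self.n_errors} skipped"
        ]
        lines += [f"  line {e.line_no}: {e.reason}" for e in self.errors]
        return "\n".join(lines)


def _build_record(kind: str, row: dict[str, str]):
    extras = {
        k: v for k, v in row.items() if k not in TABLE_COLUMNS[kind] and v != ""
    }

    def get(col: str) -> str | None:
        v = row.get(col, "").strip()
        return v or None

    if kind == "DEMO":
        age_raw = get("age")
        try:
            age = float(age_raw) if age_raw is not None else None
        except ValueError:
            age = None
        return DemoRecord(
            primaryid=row.get("primaryid", "").strip(),
            caseid=row.get("caseid", "").strip(),
            fda_dt=parse_date(row.get("fda_dt")),
            event_dt=parse_date(row.get("event_dt")),
            age=age,
            age_cod=get("age_cod"),
            sex=get("sex"),
            occp_cod=get("occp_cod"),
            occr_country=get("occr_country"),
            extras=extras,
        )
    if kind == "DRUG":
        role = get("role_cod")
        return DrugMention(
            primaryid=row.get("primaryid", "").strip(),
            drug_seq=row.get("drug_seq", "").strip(),
            drugname=_norm_ws(row.get("drugname", "")),
            prod_ai=get("prod_ai"),
            role_cod=role.upper() if role else None,
            extras=extras,
        )
    if kind == "REAC":
        return EventMention(
            primaryid=row.get("primaryid", "").strip(),
            pt=_norm_ws(row.get("pt", "")),
            extras=extras,
        )
    if kind == "OUTC":
        return OutcomeRecord(
            primaryid=row.get("primaryid", "").strip(),
            outc_cod=(get("outc_cod") or "").upper(),
            extras=extras,
        )
    if kind == "INDI":
        return IndicationRecord(
            primaryid=row.get("primaryid", "").strip(),
            indi_drug_seq=row.get("indi_drug_seq", "").strip(),
            indi_pt=_norm_ws(row.get("indi_pt", "")),
            extras=extras,
        )
    if kind == "THER":
        return TherRecord(
            primaryid=row.get("primaryid", "").strip(),
            dsg_drug_seq=row.get("dsg_drug_seq", "").strip(),
            start_dt=parse_date(row.get("start_dt")),
            extras=extras,
        )
    raise ValueError(f"unknown table kind {kind!r}")


def parse_table(stream: IO[str] | Iterable[str], table_kind: str) -> ParseResult:
    """Parse one ``$``-delimited FAERS table into typed records.

    The first line is the header; field names are matched case-insensitively
    against the canonical columns for ``table_kind`` and unknown columns are
    preserved in each record's ``extras``.  Rows whose field count differs
    from the header are skipped and surfaced as :class:`RowError` entries.

    Raises
    ------
    ValueError
        If the kind is unknown or the header is empty/unreadable.
    """
    kind = table_kind.upper()
    if kind not in TABLE_COLUMNS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    it = iter(stream)
    try:
        header_line = next(it)
    except StopIteration:
        raise ValueError(f"{kind}: missing header row") from None
    header = [h.strip().lower() for h in header_line.rstrip("\n\r").split("$")]
    if not any(header):
        raise ValueError(f"{kind}: unreadable header row")
    if "primaryid" not in header:
        raise ValueError(f"{kind}: header lacks required column 'primaryid'")

    records: list = []
    errors: list[RowError] = []
    n_rows = 0
    for line_no, line in enumerate(it, start=2):
        line = line.rstrip("\n\r")
        if not line:
            continue
        n_rows += 1
        fields = line.split("$")
        if len(fields) != len(header):
            errors.append(
                RowError(
                    line_no,
                    f"expected {len(header)} fields, found {len(fields)}",
                )
            )
            continue
        row = dict(zip(header, fields))
        rec = _build_record(kind, row)
        if not rec.primaryid:
            errors.append(RowError(line_no, "empty primaryid"))
            continue
        records.append(rec)
    return ParseResult(kind=kind, records=records, n_rows=n_rows, errors=errors)


def _render_field(rec, col: str) -> str:
    v = getattr(rec, col, None)
    if v is None:
        v = rec.extras.get(col, "")
    if isinstance(v, PartialDate):
        return v.render()
    if isinstance(v, float):
        return f"{v:g}"
    return str(v) if v is not None else ""


def write_table(records: Sequence, table_kind: str, stream: IO[str]) -> None:
    """Write records back in the same ``$``-delimited dialect (round-trips
    with :func:`parse_table`)."""
    kind = table_kind.upper()
    cols = list(TABLE_COLUMNS[kind])
    extra_cols = sorted({k for r in records for k in r.extras})
    cols += [c for c in extra_cols if c not in cols]
    stream.write("$".join(cols) + "\n")
    for rec in records:
        stream.write("$".join(_render_field(rec, c) for c in cols) + "\n")


def deduplicate(records: Sequence[DemoRecord]) -> list[DemoRecord]:
    """Keep one report version per case: latest FDA receipt date wins.

    Quarterly releases re-publish follow-up versions of earlier cases, so a
    case must be collapsed to its most recent version before any counting.
    Ties on ``fda_dt`` are broken by the larger numeric ``primaryid`` (FDA
    version numbers increase).  Deterministic and idempotent; survivors keep
    the input order of first case appearance.
    """

    def version_key(r: DemoRecord) -> tuple[int, int, str]:
        try:
            pid = int(r.primaryid)
        except ValueError:
            pid = -1
        return (r.fda_dt.sort_key(), pid, r.primaryid)

    best: dict[str, DemoRecord] = {}
    for rec in records:
        cur = best.get(rec.caseid)
        if cur is None or version_key(rec) > version_key(cur):
            best[rec.caseid] = rec
    return list(best.values())
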