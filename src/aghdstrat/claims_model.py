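"""Domain model for longitudinal administrative-claims data.

Defines the two record types the whole pipeline runs on — :class:`Person`
(one insured individual: demographics, enrollment span, vital status) and
:class:`CodedEvent` (one dated claim line: a diagnosis, procedure, or
pharmacy dispensation with its coding system) — plus the cohort window that
fixes the index date, the minimum enrollment requirement and the adult-age
cutoff, delimited-file readers/writers with per-row rejection reporting, and
the cohort-eligibility rule.

Conventions: dates are whole days and every interval is closed on both ends;
age is computed at year granularity (index year minus birth year), the
resolution claims extracts actually carry.
"""

from __future__ import annotations

import csv
import datetime
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Generic, Iterable, Mapping, Optional, Sequence, TypeVar

from .errors import ConfigurationError, InputDataError


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class CodeSystem(str, enum.Enum):
    ICD9CM = "ICD9CM"
    ICD10CM = "ICD10CM"
    CPT = "CPT"
    ATC = "ATC"


class EventKind(str, enum.Enum):
    DIAGNOSIS = "diagnosis"
    PROCEDURE = "procedure"
    PHARMACY = "pharmacy"


#: Coding systems permitted for each event kind.
KIND_SYSTEMS: Mapping[EventKind, frozenset[CodeSystem]] = {
    EventKind.DIAGNOSIS: frozenset({CodeSystem.ICD9CM, CodeSystem.ICD10CM}),
    EventKind.PROCEDURE: frozenset({CodeSystem.CPT}),
    EventKind.PHARMACY: frozenset({CodeSystem.ATC}),
}


@dataclass(frozen=True)
class Person:
    """One insured individual.

    ``death_date`` of ``None`` means alive as far as the data show.
    """

    person_id: str
    sex: Sex
    birth_year: int
    enroll_start: datetime.date
    enroll_end: datetime.date
    death_date: Optional[datetime.date] = None

    def validate(self) -> None:
        if not self.person_id:
            raise ValueError("empty person_id")
        if self.enroll_start > self.enroll_end:
            raise ValueError("inverted enrollment")
        if self.death_date is not None and self.death_date < datetime.date(
            self.birth_year, 1, 1
        ):
            raise ValueError("death before birth")


@dataclass(frozen=True)
class CodedEvent:
    """One dated claim line with its coding system.

    ``code`` is stored normalized (see :func:`aghdstrat.codelists.normalize_code`).
    """

    person_id: str
    service_date: datetime.date
    system: CodeSystem
    code: str
    kind: EventKind

    def validate(self) -> None:
        if not self.person_id:
            raise ValueError("empty person_id")
        if not self.code:
            raise ValueError("empty code")
        if self.system not in KIND_SYSTEMS[self.kind]:
            raise ValueError("kind/system mismatch")


@dataclass(frozen=True)
class CohortWindow:
    """Cohort definition: who counts as an eligible adult, and as of when.

    Defaults: index date 2017-12-31, at least 183 days (~6 months) of
    enrollment overlapping the study period, adulthood at 18 years.
    """

    index_date: datetime.date = datetime.date(2017, 12, 31)
    min_enrollment_days: int = 183
    adult_age: int = 18

    def __post_init__(self) -> None:
        if self.min_enrollment_days <= 0:
            raise ConfigurationError("min_enrollment_days must be positive")
        if self.adult_age < 0:
            raise ConfigurationError("adult_age must be >= 0")


# ---------------------------------------------------------------------------
# Delimited-file I/O with row-level rejection reporting
# ---------------------------------------------------------------------------

PERSON_COLUMNS = ("person_id", "sex", "birth_year", "enroll_start", "enroll_end", "death_date")
EVENT_COLUMNS = ("person_id", "service_date", "system", "code", "kind")

_DEFAULT_SEX_MAP = {
    "female": Sex.FEMALE,
    "male": Sex.MALE,
    "unknown": Sex.UNKNOWN,
    "f": Sex.FEMALE,
    "m": Sex.MALE,
    "": Sex.UNKNOWN,
}


@dataclass(frozen=True)
class TableDialect:
    """How a delimited file maps onto the domain model.

    ``columns`` maps the logical column name (e.g. ``person_id``) to the
    header actually present in the file; missing keys default to the literal
    logical name. ``sex_map`` maps raw sex codes (lowercased) to :class:`Sex`.
    ``date_format`` is a ``strptime`` pattern; ``None`` means ISO-8601.
    There is no sniffing: everything is declared.
    """

    delimiter: str = ","
    columns: Mapping[str, str] = field(default_factory=dict)
    sex_map: Mapping[str, Sex] = field(default_factory=lambda: dict(_DEFAULT_SEX_MAP))
    date_format: Optional[str] = None

    def column(self, logical: str) -> str:
        return self.columns.get(logical, logical)

    def parse_date(self, raw: str) -> datetime.date:
        raw = raw.strip()
        if self.date_format is None:
            return datetime.date.fromisoformat(raw)
        return datetime.datetime.strptime(raw, self.date_format).date()


DEFAULT_DIALECT = TableDialect()


@dataclass(frozen=True)
class RowRejection:
    """One input row that could not become a record, and why."""

    row_number: int  # 1-based data-row number (header not counted)
    reason: str


R = TypeVar("R")


@dataclass
class ReadResult(Generic[R]):
    """Accepted records plus rejected rows; together they account for every
    input row (``len(records) + len(rejections)`` equals the row count)."""

    records: list[R]
    rejections: list[RowRejection]

    @property
    def n_input_rows(self) -> int:
        return len(self.records) + len(self.rejections)


def _open_reader(path: Path | str, dialect: TableDialect, required: Sequence[str]):
    path = Path(path)
    if not path.exists():
        raise InputDataError(f"input file not found: {path}")
    handle = path.open(newline="")
    reader = csv.DictReader(handle, delimiter=dialect.delimiter)
    header = reader.fieldnames or []
    missing = [c for c in required if dialect.column(c) not in header]
    if missing:
        handle.close()
        raise ConfigurationError(
            f"missing mandatory column(s) {missing} in {path} (header: {header})"
        )
    return handle, reader


def read_persons(
    path: Path | str, dialect: TableDialect = DEFAULT_DIALECT
) -> ReadResult[Person]:
    """Read a persons table; malformed rows become rejection records, never
    silent drops. Row order is preserved."""
    handle, reader = _open_reader(path, dialect, PERSON_COLUMNS[:5])
    records: list[Person] = []
    rejections: list[RowRejection] = []
    with handle:
        for i, row in enumerate(reader, start=1):
            try:
                records.append(_parse_person_row(row, dialect))
            except ValueError as exc:
                rejections.append(RowRejection(i, str(exc)))
    _check_unique_ids(records)
    return ReadResult(records, rejections)


def _parse_person_row(row: Mapping[str, str], dialect: TableDialect) -> Person:
    def cell(logical: str) -> str:
        return (row.get(dialect.column(logical)) or "").strip()

    raw_sex = cell("sex").lower()
    if raw_sex not in dialect.sex_map:
        raise ValueError(f"unknown sex code {raw_sex!r}")
    try:
        birth_year = int(cell("birth_year"))
    except ValueError:
        raise ValueError("unparseable birth_year") from None
    try:
        enroll_start = dialect.parse_date(cell("enroll_start"))
        enroll_end = dialect.parse_date(cell("enroll_end"))
        raw_death = cell("death_date")
        death = dialect.parse_date(raw_death) if raw_death else None
    except ValueError:
        raise ValueError("unparseable date") from None
    person = Person(
        person_id=cell("person_id"),
        sex=dialect.sex_map[raw_sex],
        birth_year=birth_year,
        enroll_start=enroll_start,
        enroll_end=enroll_end,
        death_date=death,
    )
    person.validate()
    return person


def read_events(
    path: Path | str, dialect: TableDialect = DEFAULT_DIALECT
) -> ReadResult[CodedEvent]:
    """Read an events table; codes are normalized before storage and the
    kind/system pairing is enforced row by row."""
    from .codelists import normalize_code  # deferred: codelists imports this module

    handle, reader = _open_reader(path, dialect, EVENT_COLUMNS)
    records: list[CodedEvent] = []
    rejections: list[RowRejection] = []
    with handle:
        for i, row in enumerate(reader, start=1):
            def cell(logical: str) -> str:
                return (row.get(dialect.column(logical)) or "").strip()

            try:
                try:
                    system = CodeSystem(cell("system"))
                    kind = EventKind(cell("kind").lower())
                except ValueError:
                    raise ValueError("unknown system or kind") from None
                try:
                    service_date = dialect.parse_date(cell("service_date"))
                except ValueError:
                    raise ValueError("unparseable date") from None
                event = CodedEvent(
                    person_id=cell("person_id"),
                    service_date=service_date,
                    system=system,
                    code=normalize_code(system, cell("code")),
                    kind=kind,
                )
                event.validate()
                records.append(event)
            except ValueError as exc:
                rejections.append(RowRejection(i, str(exc)))
    return ReadResult(records, rejections)


def _check_unique_ids(persons: Iterable[Person]) -> None:
    seen: set[str] = set()
    for p in persons:
        if p.person_id in seen:
            raise InputDataError(f"duplicate person_id {p.person_id!r}")
        seen.add(p.person_id)


def write_persons(persons: Sequence[Person], path: Path | str) -> None:
    """Write a canonical persons file: literal column names, ISO dates,
    comma-delimited, empty death_date meaning alive."""
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(PERSON_COLUMNS)
        for p in persons:
            writer.writerow(
                [
                    p.person_id,
                    p.sex.value,
                    p.birth_year,
                    p.enroll_start.isoformat(),
                    p.enroll_end.isoformat(),
                    p.death_date.isoformat() if p.death_date else "",
                ]
            )


def write_events(events: Sequence[CodedEvent], path: Path | str) -> None:
    """Write a canonical events file (ISO dates, comma-delimited)."""
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(EVENT_COLUMNS)
        for e in events:
            writer.writerow(
                [e.person_id, e.service_date.isoformat(), e.system.value, e.code, e.kind.value]
            )


def write_rejections(rejections: Sequence[RowRejection], path: Path | str) -> None:
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(("row_number", "reason"))
        for r in rejections:
            writer.writerow((r.row_number, r.reason))


# ---------------------------------------------------------------------------
# Cohort eligibility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Eligibility:
    eligible: bool
    reason: Optional[str]  # first failed criterion: "age" | "enrollment" | "deceased"


def eligible(person: Person, window: CohortWindow) -> Eligibility:
    """Adult at the index date, with enough enrollment, and alive.

    A person qualifies when index-year age is at least ``adult_age``, the
    enrollment span clipped at the index date covers at least
    ``min_enrollment_days`` (closed interval, so a single day counts as 1),
    and any death date falls strictly after the index date. The reason names
    the first criterion that fails, checked in the order age, enrollment,
    vital status.
    """
    if window.index_date.year - person.birth_year < window.adult_age:
        return Eligibility(False, "age")
    clipped_end = min(person.enroll_end, window.index_date)
    days = (clipped_end - person.enroll_start).days + 1
    if days < window.min_enrollment_days:
        return Eligibility(False, "enrollment")
    if person.death_date is not None and person.death_date <= window.index_date:
        return Eligibility(False, "deceased")
    return Eligibility(True, None)


def observation_bounds(
    person: Person,
    events: Sequence[CodedEvent],
    window: CohortWindow,
) -> tuple[datetime.date, datetime.date]:
    """The observed interval for a person: enrollment start through the
    earlier of enrollment end and the index date. Events only sanity-check
    ownership; bounds come from enrollment, so they exist with zero claims.
    """
    for e in events:
        if e.person_id != person.person_id:
            raise InputDataError(
                f"event person_id {e.person_id!r} does not match {person.person_id!r}"
            )
    return person.enroll_start, min(person.enroll_end, window.index_date)


__all__ = [
    "Sex",
    "CodeSystem",
    "EventKind",
    "KIND_SYSTEMS",
    "Person",
    "CodedEvent",
    "CohortWindow",
    "TableDialect",
    "DEFAULT_DIALECT",
    "RowRejection",
    "ReadResult",
    "read_persons",
    "read_events",
    "write_persons",
    "write_events",
    "write_rejections",
    "Eligibility",
    "eligible",
    "observation_bounds",
    "PERSON_COLUMNS",
    "EVENT_COLUMNS",
]
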