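"""Domain model for linac schedule analytics.

Schedules are collections of timed, categorised events on linear
accelerators (linacs).  Time-of-day is integer minutes from midnight and
every appointment is a half-open interval ``[start, end)`` — this makes
back-to-back slots (e.g. ``[540, 555)`` then ``[555, 570)``) unambiguous
and keeps all interval arithmetic exact.

The module provides

* configuration types (:class:`LinacConfig`, :class:`DepartmentConfig`),
* the event/snapshot types (:class:`ScheduleEvent`, :class:`Snapshot`),
* schedule validation and the interval/calendar primitives every other
  module builds on (:func:`validate_events`, :func:`clip_to_window`,
  :func:`weekday_horizon`),
* CSV/JSON round-trip for the external event and config formats and the
  daily snapshot-archive layout (``YYYY-MM-DD_planned.csv`` /
  ``YYYY-MM-DD_observed.csv``).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "TREATMENT",
    "NON_TREATMENT",
    "TREATMENT_SUBCATEGORIES",
    "NON_TREATMENT_SUBCATEGORIES",
    "NT_TIE_ORDER",
    "SUBCATEGORY_MAIN",
    "WEEKDAY_KEYS",
    "ScheduleError",
    "OverlapError",
    "UnknownLinacError",
    "CalendarError",
    "SnapshotMismatchError",
    "EmptyAggregateError",
    "DegenerateError",
    "ZeroTotalError",
    "EmptyArchiveError",
    "RankDeficiencyError",
    "MissingSnapshotError",
    "CapacityExhaustedError",
    "LinacConfig",
    "DepartmentConfig",
    "ScheduleEvent",
    "Snapshot",
    "parse_hhmm",
    "format_hhmm",
    "validate_events",
    "clip_to_window",
    "weekday_horizon",
    "read_events_csv",
    "write_events_csv",
    "events_to_frame",
    "frame_to_events",
    "snapshot_path",
    "load_snapshot",
    "list_snapshot_dates",
    "iter_snapshots",
]

# --------------------------------------------------------------------------
# Category taxonomy
# --------------------------------------------------------------------------

TREATMENT = "Treatment"
NON_TREATMENT = "NonTreatment"

#: Subcategories counted as linac time dedicated to patients.  "Pre-booked"
#: is a placeholder slot reserved for standardised care-path patients before
#: a specific patient is assigned; it converts to "Treatment" when claimed.
TREATMENT_SUBCATEGORIES: tuple[str, ...] = ("Pre-booked", "Treatment")

NON_TREATMENT_SUBCATEGORIES: tuple[str, ...] = (
    "Break",
    "Education",
    "LinacQA",
    "Maintenance",
    "Meetings",
    "PatientQA",
    "Preparation",
)

#: Fixed tie-break order when attributing a non-treatment increase to the
#: dominant subcategory (large disruptions are typically machine downtime,
#: small ones patient-plan QA).
NT_TIE_ORDER: tuple[str, ...] = (
    "Maintenance",
    "PatientQA",
    "LinacQA",
    "Preparation",
    "Meetings",
    "Education",
    "Break",
)

SUBCATEGORY_MAIN: dict[str, str] = {
    **{s: TREATMENT for s in TREATMENT_SUBCATEGORIES},
    **{s: NON_TREATMENT for s in NON_TREATMENT_SUBCATEGORIES},
}

WEEKDAY_KEYS: tuple[str, ...] = ("Mon", "Tue", "Wed", "Thu", "Fri")

EVENT_CSV_COLUMNS: tuple[str, ...] = (
    "linac_id",
    "date",
    "start",
    "end",
    "main_category",
    "subcategory",
    "status",
    "no_show",
    "patient_id",
    "series_id",
    "fraction_no",
)


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------


class ScheduleError(Exception):
    """Base class for all domain errors raised by this package."""


class OverlapError(ScheduleError):
    """Two events on the same linac intersect in time.

    A physical linac hosts one activity at a time, so an overlap in an
    export is treated as corrupt data rather than silently merged.
    """


class UnknownLinacError(ScheduleError):
    """An event references a linac id absent from the department config."""


class CalendarError(ScheduleError):
    """A date falls outside the operating calendar (weekend or holiday)."""


class SnapshotMismatchError(ScheduleError):
    """Planned/observed snapshots do not refer to the same day."""


class EmptyAggregateError(ScheduleError):
    """Aggregation requested over an empty set of per-linac metrics."""


class DegenerateError(ScheduleError):
    """A paired test has no information (all differences are zero)."""


class ZeroTotalError(ScheduleError):
    """A percentage was requested with a zero denominator."""


class EmptyArchiveError(ScheduleError):
    """A snapshot archive contains no snapshots."""


class RankDeficiencyError(ScheduleError):
    """Too few points to fit the requested polynomial degree."""


class MissingSnapshotError(ScheduleError):
    """No snapshot file exists for the requested date."""


class CapacityExhaustedError(ScheduleError):
    """No feasible booking exists for a full series within the horizon."""


# --------------------------------------------------------------------------
# Time helpers
# --------------------------------------------------------------------------


def parse_hhmm(text: str) -> int:
    """Parse ``"HH:MM"`` into minutes from midnight."""
    hh, mm = text.strip().split(":")
    minutes = int(hh) * 60 + int(mm)
    if not 0 <= minutes < 24 * 60:
        raise ValueError(f"time of day out of range: {text!r}")
    return minutes


def format_hhmm(minutes: int) -> str:
    """Format minutes from midnight as ``"HH:MM"`` (1440 allowed as 24:00)."""
    if not 0 <= minutes <= 24 * 60:
        raise ValueError(f"minutes out of range: {minutes}")
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


def is_weekday(date: dt.date) -> bool:
    return date.weekday() < 5


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


class LinacConfig(BaseModel):
    """One linac: identity, treatment-equivalent group, opening windows.

    ``weekday_windows`` maps ``"Mon".."Fri"`` to ``(open, close)`` in
    minutes from midnight.  Windows exist only for weekdays — the
    department operates Monday to Friday.
    """

    linac_id: str
    group_id: str
    weekday_windows: dict[str, tuple[int, int]]

    @field_validator("linac_id")
    @classmethod
    def _nonempty_id(cls, v: str) -> str:
        if not v:
            raise ValueError("linac_id must be non-empty")
        return v

    @field_validator("weekday_windows", mode="before")
    @classmethod
    def _parse_windows(cls, v):
        if isinstance(v, dict):
            parsed = {}
            for key, win in v.items():
                o, c = win
                parsed[key] = (
                    parse_hhmm(o) if isinstance(o, str) else int(o),
                    parse_hhmm(c) if isinstance(c, str) else int(c),
                )
            return parsed
        return v

    @field_validator("weekday_windows")
    @classmethod
    def _check_windows(cls, v: dict[str, tuple[int, int]]):
        for key, (o, c) in v.items():
            if key not in WEEKDAY_KEYS:
                raise ValueError(f"window key {key!r} is not a weekday Mon..Fri")
            if not o < c:
                raise ValueError(f"window for {key} has open >= close ({o} >= {c})")
        missing = [k for k in WEEKDAY_KEYS if k not in v]
        if missing:
            raise ValueError(f"missing weekday windows: {missing}")
        return v

    def window(self, date: dt.date) -> tuple[int, int]:
        """Opening window ``(open, close)`` for a weekday date."""
        if not is_weekday(date):
            raise CalendarError(f"{date} is not a weekday")
        return self.weekday_windows[WEEKDAY_KEYS[date.weekday()]]


class DepartmentConfig(BaseModel):
    """The machine park and the daily snapshot protocol.

    The planned schedule is captured once per weekday morning (default
    06:00) before clinical work starts, and the observed schedule after
    the day's work has finished (default 21:00).
    """

    linacs: list[LinacConfig]
    planned_snapshot_time: int = 6 * 60
    observed_snapshot_time: int = 21 * 60
    horizon_weekdays: int = 100
    holidays: list[dt.date] = Field(default_factory=list)

    @field_validator("planned_snapshot_time", "observed_snapshot_time", mode="before")
    @classmethod
    def _parse_time(cls, v):
        return parse_hhmm(v) if isinstance(v, str) else v

    @model_validator(mode="after")
    def _check(self) -> "DepartmentConfig":
        ids = [l.linac_id for l in self.linacs]
        if len(ids) != len(set(ids)):
            raise ValueError("linac_ids must be unique")
        if not self.planned_snapshot_time < self.observed_snapshot_time:
            raise ValueError("planned snapshot must precede the observed snapshot")
        if self.horizon_weekdays < 1:
            raise ValueError("horizon_weekdays must be >= 1")
        return self

    # -- lookup helpers ----------------------------------------------------

    @property
    def linac_ids(self) -> list[str]:
        return [l.linac_id for l in self.linacs]

    @property
    def group_ids(self) -> list[str]:
        seen: list[str] = []
        for l in self.linacs:
            if l.group_id not in seen:
                seen.append(l.group_id)
        return seen

    def linac(self, linac_id: str) -> LinacConfig:
        for l in self.linacs:
            if l.linac_id == linac_id:
                return l
        raise UnknownLinacError(f"unknown linac id {linac_id!r}")

    def group_members(self, group_id: str) -> list[str]:
        members = [l.linac_id for l in self.linacs if l.group_id == group_id]
        if not members:
            raise UnknownLinacError(f"unknown group id {group_id!r}")
        return members

    def entity_members(self, entity_id: str) -> list[str]:
        """Linac ids behind an entity: a linac id, a group id, or ``"park"``."""
        if entity_id == "park":
            return self.linac_ids
        if entity_id in self.linac_ids:
            return [entity_id]
        return self.group_members(entity_id)

    def is_open_day(self, date: dt.date) -> bool:
        return is_weekday(date) and date not in self.holidays

    # -- JSON round trip ---------------------------------------------------

    @classmethod
    def from_json(cls, path: str | Path) -> "DepartmentConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        payload = self.model_dump(mode="json")
        # emit windows and snapshot times as HH:MM for readability
        for linac in payload["linacs"]:
            linac["weekday_windows"] = {
                k: [format_hhmm(o), format_hhmm(c)]
                for k, (o, c) in linac["weekday_windows"].items()
            }
        payload["planned_snapshot_time"] = format_hhmm(self.planned_snapshot_time)
        payload["observed_snapshot_time"] = format_hhmm(self.observed_snapshot_time)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


# --------------------------------------------------------------------------
# Events and snapshots
# --------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class ScheduleEvent:
    """One timed, categorised activity on one linac.

    ``start``/``end`` are minutes from midnight; the interval is half-open
    ``[start, end)`` and must not span midnight.  ``no_show`` marks a
    treatment slot where the patient did not attend (the slot stays in the
    schedule but is excluded from treatment hours).
    """

    linac_id: str
    date: dt.date
    start: int
    end: int
    main_category: str
    subcategory: str
    status: str = "planned"
    no_show: bool = False
    patient_id: str | None = None
    series_id: str | None = None
    fraction_no: int | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"inverted interval [{self.start}, {self.end}) on {self.linac_id}"
            )
        if self.end > 24 * 60:
            raise ValueError("events must not span midnight")
        expected = SUBCATEGORY_MAIN.get(self.subcategory)
        if expected is None:
            raise ValueError(f"unknown subcategory {self.subcategory!r}")
        if expected != self.main_category:
            raise ValueError(
                f"subcategory {self.subcategory!r} belongs to {expected}, "
                f"not {self.main_category}"
            )
        if self.status not in ("planned", "observed"):
            raise ValueError(f"status must be planned|observed, got {self.status!r}")
        if self.no_show and self.subcategory != "Treatment":
            raise ValueError("no_show applies only to Treatment slots")

    @property
    def duration(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Snapshot:
    """All events captured at one point in time.

    A morning (planned) snapshot spans the capture day — Day 0 — plus the
    forthcoming planning horizon of weekdays; an evening (observed)
    snapshot records what actually happened on Day 0.
    """

    as_of: dt.date
    kind: str  # "planned" | "observed"
    events: tuple[ScheduleEvent, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("planned", "observed"):
            raise ValueError(f"snapshot kind must be planned|observed: {self.kind!r}")
        object.__setattr__(self, "events", tuple(self.events))
        for ev in self.events:
            if ev.date < self.as_of:
                raise ValueError(
                    f"event on {ev.date} predates snapshot as-of {self.as_of}"
                )
            if not is_weekday(ev.date):
                raise ValueError(f"event on non-weekday {ev.date}")

    def day0_events(self) -> tuple[ScheduleEvent, ...]:
        return tuple(ev for ev in self.events if ev.date == self.as_of)

    def events_on(self, date: dt.date) -> tuple[ScheduleEvent, ...]:
        return tuple(ev for ev in self.events if ev.date == date)


# --------------------------------------------------------------------------
# Core operations
# --------------------------------------------------------------------------


def validate_events(
    events: Sequence[ScheduleEvent], config: DepartmentConfig
) -> Sequence[ScheduleEvent]:
    """Check a batch of events against the department configuration.

    Returns the events unchanged when valid.  Raises
    :class:`UnknownLinacError` for ids outside the machine park,
    :class:`CalendarError` for weekend/holiday dates, and
    :class:`OverlapError` when two events on the same linac and day
    intersect (half-open interval intersection).
    """
    known = set(config.linac_ids)
    by_day: dict[tuple[str, dt.date], list[ScheduleEvent]] = {}
    for ev in events:
        if ev.linac_id not in known:
            raise UnknownLinacError(f"unknown linac id {ev.linac_id!r}")
        if not config.is_open_day(ev.date):
            raise CalendarError(f"{ev.date} is not an operating day")
        by_day.setdefault((ev.linac_id, ev.date), []).append(ev)
    for (linac_id, date), day_events in by_day.items():
        ordered = sorted(day_events, key=lambda e: (e.start, e.end))
        for prev, cur in zip(ordered, ordered[1:]):
            if cur.start < prev.end:  # half-open intervals intersect
                raise OverlapError(
                    f"events overlap on {linac_id} {date}: "
                    f"[{format_hhmm(prev.start)},{format_hhmm(prev.end)}) and "
                    f"[{format_hhmm(cur.start)},{format_hhmm(cur.end)})"
                )
    return events


def clip_to_window(
    event: ScheduleEvent, window: tuple[int, int]
) -> tuple[int, int]:
    """Split an event's duration into minutes inside/outside an opening window.

    Returns ``(minutes_within, minutes_outside)`` with
    ``minutes_within + minutes_outside == event.duration``;
    ``minutes_within`` is the length of ``[start, end) ∩ [open, close)``.
    """
    lo, hi = window
    within = max(0, min(event.end, hi) - max(event.start, lo))
    return within, event.duration - within


def weekday_horizon(
    as_of: dt.date, h: int, holidays: Iterable[dt.date] = ()
) -> list[dt.date]:
    """The ``h + 1`` operating weekdays starting at ``as_of`` (inclusive).

    Saturdays, Sundays and any supplied holidays are skipped, so the last
    element is the date lying ``h`` planning-horizon weekdays ahead.
    """
    if not is_weekday(as_of):
        raise CalendarError(f"{as_of} is not a weekday")
    if h < 0:
        raise ValueError("horizon must be >= 0")
    skip = set(holidays)
    if as_of in skip:
        raise CalendarError(f"{as_of} is a holiday")
    out = [as_of]
    d = as_of
    while len(out) < h + 1:
        d += dt.timedelta(days=1)
        if is_weekday(d) and d not in skip:
            out.append(d)
    return out


# --------------------------------------------------------------------------
# Event CSV and snapshot archive I/O
# --------------------------------------------------------------------------


def events_to_frame(events: Iterable[ScheduleEvent]) -> pd.DataFrame:
    rows = [
        (
            ev.linac_id,
            ev.date.isoformat(),
            format_hhmm(ev.start),
            format_hhmm(ev.end),
            ev.main_category,
            ev.subcategory,
            ev.status,
            ev.no_show,
            ev.patient_id if ev.patient_id is not None else "",
            ev.series_id if ev.series_id is not None else "",
            ev.fraction_no if ev.fraction_no is not None else "",
        )
        for ev in events
    ]
    return pd.DataFrame(rows, columns=list(EVENT_CSV_COLUMNS))


def frame_to_events(frame: pd.DataFrame) -> list[ScheduleEvent]:
    def _opt(value) -> str | None:
        if value is None or (isinstance(value, float) and pd.isna(value)):
            return None
        text = str(value).strip()
        return text or None

    events = []
    for row in frame.itertuples(index=False):
        fraction = _opt(row.fraction_no)
        events.append(
            ScheduleEvent(
                linac_id=str(row.linac_id),
                date=dt.date.fromisoformat(str(row.date)),
                start=parse_hhmm(str(row.start)),
                end=parse_hhmm(str(row.end)),
                main_category=str(row.main_category),
                subcategory=str(row.subcategory),
                status=str(row.status),
                no_show=str(row.no_show).strip().lower() in ("true", "1"),
                patient_id=_opt(row.patient_id),
                series_id=_opt(row.series_id),
                fraction_no=int(float(fraction)) if fraction is not None else None,
            )
        )
    return events


def write_events_csv(events: Iterable[ScheduleEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[ScheduleEvent]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"event CSV {path} missing columns {missing}")
    return frame_to_events(frame)


def snapshot_path(archive_dir: str | Path, date: dt.date, kind: str) -> Path:
    return Path(archive_dir) / f"{date.isoformat()}_{kind}.csv"


def load_snapshot(
    archive_dir: str | Path,
    date: dt.date,
    kind: str,
    config: DepartmentConfig | None = None,
) -> Snapshot:
    """Load one day's planned or observed snapshot from an archive directory."""
    path = snapshot_path(archive_dir, date, kind)
    if not path.exists():
        raise MissingSnapshotError(f"no {kind} snapshot for {date} in {archive_dir}")
    events = read_events_csv(path)
    if config is not None:
        validate_events(events, config)
    return Snapshot(as_of=date, kind=kind, events=tuple(events))


def list_snapshot_dates(archive_dir: str | Path, kind: str = "planned") -> list[dt.date]:
    suffix = f"_{kind}.csv"
    dates = [
        dt.date.fromisoformat(p.name[: -len(suffix)])
        for p in sorted(Path(archive_dir).glob(f"*{suffix}"))
    ]
    return dates


def iter_snapshots(
    archive_dir: str | Path,
    kind: str = "planned",
    config: DepartmentConfig | None = None,
) -> Iterator[Snapshot]:
    """Stream snapshots of one kind from an archive, ordered by date."""
    for date in list_snapshot_dates(archive_dir, kind):
        yield load_snapshot(archive_dir, date, kind, config)
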