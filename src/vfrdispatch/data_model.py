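"""Entities and CSV input/output for volunteer first-responder (VFR) alert logs.

A VFR network log has three entity kinds:

* :class:`Volunteer` — a network member with demographics and
  condition-specific experience (here, opioid-overdose response).
* :class:`Event` — one emergency, reported by a *signaler* (who is also a
  network member); carries a false-alarm flag and a time context.
* :class:`Alert` — one notification sent to one volunteer (the *responder*)
  about one event, with a distance to the scene and a final status.

An :class:`AlertLog` bundles the three, keeps alerts globally ordered by
``(alert_time, alert_id)``, and is the in-memory container every other
module consumes.  Logs round-trip losslessly through three CSV files
(``volunteers.csv``, ``events.csv``, ``alerts.csv``; RFC-4180, UTF-8,
header row, booleans as ``true``/``false``, missing values as empty
strings).
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GENDERS", "EMPLOYMENT", "CARRIAGE", "BANDS", "FINAL_STATUSES",
    "ANSWERED_STATUSES", "DAY_START_HOUR", "DAY_END_HOUR",
    "day_night", "weekday_weekend",
    "Volunteer", "Event", "Alert", "AlertLog",
    "ParseError", "Violation", "parse_alert_log", "write_alert_log",
    "validate_log",
]

GENDERS = ("male", "female", "intersex")
EMPLOYMENT = ("part_time", "full_time", "unemployed")
CARRIAGE = ("all_the_time", "often", "sometimes", "seldom", "never")
BANDS = ("<=20", "21-40", ">40")
FINAL_STATUSES = ("no_answer", "no_go", "en_route", "on_scene", "done",
                  "canceled_dispatch")
#: Statuses counted as "the volunteer answered the alert".
ANSWERED_STATUSES = tuple(s for s in FINAL_STATUSES if s != "no_answer")

# Calendar convention (stored explicitly so it is overridable): "day" is
# 06:00-17:59 local clock time, "night" otherwise; "weekend" is Saturday
# or Sunday.  Timestamps are integer seconds UTC and the convention is
# applied to the UTC clock.
DAY_START_HOUR = 6
DAY_END_HOUR = 18


def _dt(timestamp: int) -> datetime:
    return datetime.fromtimestamp(int(timestamp), tz=timezone.utc)


def day_night(timestamp: int) -> str:
    """Classify a timestamp as ``"day"`` (06:00-17:59) or ``"night"``."""
    return "day" if DAY_START_HOUR <= _dt(timestamp).hour < DAY_END_HOUR else "night"


def weekday_weekend(timestamp: int) -> str:
    """Classify a timestamp as ``"weekday"`` (Mon-Fri) or ``"weekend"``."""
    return "weekend" if _dt(timestamp).weekday() >= 5 else "weekday"


@dataclass(frozen=True)
class Volunteer:
    """A network member; demographics follow the study's questionnaire bands."""

    volunteer_id: str
    age: int
    gender: str                  # one of GENDERS
    homeless: bool
    employment: str              # one of EMPLOYMENT
    naloxone_carriage: str       # one of CARRIAGE (ordinal, most to least)
    witnessed_band: str          # BANDS: overdoses witnessed before joining
    administered_band: str       # BANDS: naloxone administrations before joining


@dataclass(frozen=True)
class Event:
    """One emergency event reported by a signaler.

    ``weekday_weekend`` and ``day_night`` are derived from ``timestamp``
    under the module's calendar convention, so they always agree with it.
    """

    event_id: str
    timestamp: int               # seconds since epoch, UTC
    false_alarm: bool
    signaler_id: str

    @property
    def weekday_weekend(self) -> str:
        return weekday_weekend(self.timestamp)

    @property
    def day_night(self) -> str:
        return day_night(self.timestamp)


@dataclass(frozen=True)
class Alert:
    """One notification to one responder about one event.

    ``distance_m`` is the responder's distance to the scene in meters;
    ``None`` means unknown (distances were unavailable for 13.8% of the
    study's events), deliberately distinct from 0, which is a valid datum.
    """

    alert_id: str
    event_id: str
    responder_id: str
    alert_time: int              # seconds since epoch, UTC
    distance_m: float | None
    final_status: str            # one of FINAL_STATUSES

    @property
    def answered(self) -> bool:
        return self.final_status != "no_answer"

    def sort_key(self) -> tuple[int, str]:
        return (self.alert_time, self.alert_id)


@dataclass
class AlertLog:
    """Roster + events + globally ordered alert sequence."""

    volunteers: dict[str, Volunteer] = field(default_factory=dict)
    events: dict[str, Event] = field(default_factory=dict)
    alerts: list[Alert] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sort_alerts()

    def sort_alerts(self) -> None:
        """Sort alerts by ``(alert_time, alert_id)``; stable and idempotent."""
        self.alerts.sort(key=Alert.sort_key)

    def event_of(self, alert: Alert) -> Event:
        return self.events[alert.event_id]

    def volunteer_of(self, alert: Alert) -> Volunteer:
        return self.volunteers[alert.responder_id]

    @property
    def n_alerts(self) -> int:
        return len(self.alerts)


class ParseError(ValueError):
    """Raised on malformed input; names the file, row and column."""

    def __init__(self, file: str, row: int, column: str, message: str):
        self.file, self.row, self.column = file, row, column
        super().__init__(f"{file}, row {row}, column {column!r}: {message}")


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_log`."""

    entity_id: str
    rule: str
    message: str


_VOLUNTEER_COLUMNS = ("volunteer_id", "age", "gender", "homeless", "employment",
                      "naloxone_carriage", "witnessed_band", "administered_band")
_EVENT_COLUMNS = ("event_id", "timestamp", "false_alarm", "signaler_id")
_ALERT_COLUMNS = ("alert_id", "event_id", "responder_id", "alert_time",
                  "distance_m", "final_status")


def _read_rows(path: str | Path, columns: Sequence[str]) -> list[dict[str, str]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(path.name, 0, "", "empty file, expected a header row")
        if tuple(header) != tuple(columns):
            raise ParseError(path.name, 0, "", f"expected header {list(columns)}, got {header}")
        rows = []
        for i, raw in enumerate(reader, start=1):
            if len(raw) != len(columns):
                raise ParseError(path.name, i, "", f"expected {len(columns)} fields, got {len(raw)}")
            rows.append(dict(zip(columns, raw)))
        return rows


def _parse_int(value: str, file: str, row: int, column: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(file, row, column, f"not an integer: {value!r}") from None


def _parse_bool(value: str, file: str, row: int, column: str) -> bool:
    if value == "true":
        return True
    if value == "false":
        return False
    raise ParseError(file, row, column, f"expected 'true' or 'false', got {value!r}")


def _parse_enum(value: str, allowed: Sequence[str], file: str, row: int, column: str) -> str:
    if value not in allowed:
        raise ParseError(file, row, column, f"unknown token {value!r}, expected one of {list(allowed)}")
    return value


def parse_alert_log(volunteers_path: str | Path,
                    events_path: str | Path,
                    alerts_path: str | Path) -> AlertLog:
    """Parse the three log CSVs into an :class:`AlertLog`.

    Raises :class:`ParseError` (naming file, row and column) on unknown
    status tokens, dangling references, or malformed values.  Referential
    integrity is checked here; softer invariants are left to
    :func:`validate_log` so that they surface as data, not exceptions.
    """
    vfile = Path(volunteers_path).name
    efile = Path(events_path).name
    afile = Path(alerts_path).name

    volunteers: dict[str, Volunteer] = {}
    for i, row in enumerate(_read_rows(volunteers_path, _VOLUNTEER_COLUMNS), start=1):
        v = Volunteer(
            volunteer_id=row["volunteer_id"],
            age=_parse_int(row["age"], vfile, i, "age"),
            gender=_parse_enum(row["gender"], GENDERS, vfile, i, "gender"),
            homeless=_parse_bool(row["homeless"], vfile, i, "homeless"),
            employment=_parse_enum(row["employment"], EMPLOYMENT, vfile, i, "employment"),
            naloxone_carriage=_parse_enum(row["naloxone_carriage"], CARRIAGE, vfile, i, "naloxone_carriage"),
            witnessed_band=_parse_enum(row["witnessed_band"], BANDS, vfile, i, "witnessed_band"),
            administered_band=_parse_enum(row["administered_band"], BANDS, vfile, i, "administered_band"),
        )
        volunteers[v.volunteer_id] = v

    events: dict[str, Event] = {}
    for i, row in enumerate(_read_rows(events_path, _EVENT_COLUMNS), start=1):
        e = Event(
            event_id=row["event_id"],
            timestamp=_parse_int(row["timestamp"], efile, i, "timestamp"),
            false_alarm=_parse_bool(row["false_alarm"], efile, i, "false_alarm"),
            signaler_id=row["signaler_id"],
        )
        if e.signaler_id not in volunteers:
            raise ParseError(efile, i, "signaler_id", f"unknown volunteer {e.signaler_id!r}")
        events[e.event_id] = e

    alerts: list[Alert] = []
    for i, row in enumerate(_read_rows(alerts_path, _ALERT_COLUMNS), start=1):
        distance: float | None
        if row["distance_m"] == "":
            distance = None
        else:
            try:
                distance = float(row["distance_m"])
            except ValueError:
                raise ParseError(afile, i, "distance_m", f"not a number: {row['distance_m']!r}") from None
        a = Alert(
            alert_id=row["alert_id"],
            event_id=row["event_id"],
            responder_id=row["responder_id"],
            alert_time=_parse_int(row["alert_time"], afile, i, "alert_time"),
            distance_m=distance,
            final_status=_parse_enum(row["final_status"], FINAL_STATUSES, afile, i, "final_status"),
        )
        if a.event_id not in events:
            raise ParseError(afile, i, "event_id", f"unknown event {a.event_id!r}")
        if a.responder_id not in volunteers:
            raise ParseError(afile, i, "responder_id", f"unknown volunteer {a.responder_id!r}")
        alerts.append(a)

    return AlertLog(volunteers=volunteers, events=events, alerts=alerts)


def _fmt_bool(value: bool) -> str:
    return "true" if value else "false"


def _fmt_distance(value: float | None) -> str:
    if value is None:
        return ""
    # Integers render without a trailing .0 so round-trips are textual too.
    return repr(int(value)) if float(value).is_integer() else repr(float(value))


def write_alert_log(log: AlertLog, out_dir: str | Path) -> dict[str, Path]:
    """Write ``volunteers.csv``, ``events.csv``, ``alerts.csv`` under *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.csv" for name in ("volunteers", "events", "alerts")}

    with paths["volunteers"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_VOLUNTEER_COLUMNS)
        for v in sorted(log.volunteers.values(), key=lambda v: v.volunteer_id):
            w.writerow([v.volunteer_id, v.age, v.gender, _fmt_bool(v.homeless),
                        v.employment, v.naloxone_carriage, v.witnessed_band,
                        v.administered_band])

    with paths["events"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_EVENT_COLUMNS)
        for e in sorted(log.events.values(), key=lambda e: (e.timestamp, e.event_id)):
            w.writerow([e.event_id, e.timestamp, _fmt_bool(e.false_alarm), e.signaler_id])

    with paths["alerts"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_ALERT_COLUMNS)
        for a in log.alerts:
            w.writerow([a.alert_id, a.event_id, a.responder_id, a.alert_time,
                        _fmt_distance(a.distance_m), a.final_status])
    return paths


def validate_log(log: AlertLog) -> list[Violation]:
    """Check every log invariant; returns violations as data (never raises).

    Rules checked: volunteer field domains and ``age >= 18``; alert/event
    referential integrity; ``alert_time >= event.timestamp``; a signaler
    never alerted for their own event; non-negative distances; valid final
    statuses; unique alert ids; at most one alert per (event, responder)
    pair; global ``(alert_time, alert_id)`` ordering.
    """
    out: list[Violation] = []

    for v in log.volunteers.values():
        if v.age < 18:
            out.append(Violation(v.volunteer_id, "age_minimum", f"age {v.age} < 18"))
        for attr, allowed in (("gender", GENDERS), ("employment", EMPLOYMENT),
                              ("naloxone_carriage", CARRIAGE),
                              ("witnessed_band", BANDS), ("administered_band", BANDS)):
            if getattr(v, attr) not in allowed:
                out.append(Violation(v.volunteer_id, f"{attr}_domain",
                                     f"{attr}={getattr(v, attr)!r} not in {list(allowed)}"))

    for e in log.events.values():
        if e.signaler_id not in log.volunteers:
            out.append(Violation(e.event_id, "signaler_exists",
                                 f"signaler {e.signaler_id!r} not in roster"))

    seen_ids: set[str] = set()
    seen_pairs: set[tuple[str, str]] = set()
    for a in log.alerts:
        if a.alert_id in seen_ids:
            out.append(Violation(a.alert_id, "unique_alert_id", "duplicate alert_id"))
        seen_ids.add(a.alert_id)
        if a.final_status not in FINAL_STATUSES:
            out.append(Violation(a.alert_id, "final_status_domain",
                                 f"unknown status {a.final_status!r}"))
        if a.distance_m is not None and a.distance_m < 0:
            out.append(Violation(a.alert_id, "distance_nonnegative",
                                 f"distance {a.distance_m} < 0"))
        if a.event_id not in log.events:
            out.append(Violation(a.alert_id, "event_exists",
                                 f"unknown event {a.event_id!r}"))
            continue
        if a.responder_id not in log.volunteers:
            out.append(Violation(a.alert_id, "responder_exists",
                                 f"unknown volunteer {a.responder_id!r}"))
            continue
        event = log.events[a.event_id]
        if a.alert_time < event.timestamp:
            out.append(Violation(a.alert_id, "alert_after_event",
                                 f"alert_time {a.alert_time} precedes event at {event.timestamp}"))
        if a.responder_id == event.signaler_id:
            out.append(Violation(a.alert_id, "responder_not_signaler",
                                 "alert sent to the event's own signaler"))
        pair = (a.event_id, a.responder_id)
        if pair in seen_pairs:
            out.append(Violation(a.alert_id, "one_alert_per_event_responder",
                                 f"repeat alert for pair {pair}"))
        seen_pairs.add(pair)

    keys = [a.sort_key() for a in log.alerts]
    if keys != sorted(keys):
        out.append(Violation("<log>", "alerts_ordered",
                             "alerts not sorted by (alert_time, alert_id)"))
    return out
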