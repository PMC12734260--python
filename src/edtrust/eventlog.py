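"""Structured event log: the simulation's complete, replayable record.

Every run emits an ordered sequence of records with non-decreasing timestamps;
the metric layer is a pure function of this stream, so replaying a written CSV
reproduces the run's metrics bit-exactly.  Floats are serialized with ``repr``
(round-trip exact) and the ``detail`` column carries ``key=value`` pairs
separated by ``;``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

COLUMNS = ("time_s", "event", "actor", "bed", "request", "level", "detail")

# event kinds, in rough lifecycle order
DOCTOR_SPAWN = "doctor_spawn"
NURSE_SPAWN = "nurse_spawn"
TRAINER_SPAWN = "trainer_spawn"
PATIENT_SPAWN = "patient_spawn"
EXAM_START = "exam_start"
REQUEST_ISSUED = "request_issued"
CLAIM = "claim"
ARRIVE = "arrive"
ABANDON = "abandon"
EXECUTE_START = "execute_start"
TASK_COMPLETE = "task_complete"
NURSE_HOME = "nurse_home"
SELF_ASSESS_UNRELIABLE = "self_assess_unreliable"
REPLACEMENT_SPAWN = "replacement_spawn"
TRAINING_PROGRESS = "training_progress"
TRAINER_EXIT = "trainer_exit"
SHIFT_END = "shift_end"


class EventLogError(ValueError):
    """A malformed or inconsistent event log (carries the offending line)."""


@dataclass(frozen=True)
class EventRecord:
    time_s: float
    event: str
    actor: Optional[int] = None
    bed: Optional[int] = None
    request: Optional[int] = None
    level: Optional[int] = None
    detail: dict = field(default_factory=dict)

    def detail_str(self) -> str:
        return ";".join(f"{k}={_render(v)}" for k, v in self.detail.items())


def _render(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_detail(text: str) -> dict:
    out: dict = {}
    if not text:
        return out
    for pair in text.split(";"):
        key, _, raw = pair.partition("=")
        if raw in ("true", "false"):
            out[key] = raw == "true"
            continue
        try:
            out[key] = int(raw)
        except ValueError:
            try:
                out[key] = float(raw)
            except ValueError:
                out[key] = raw
    return out


class EventLog:
    """An append-only, time-ordered list of :class:`EventRecord`."""

    def __init__(self, records: Iterable[EventRecord] = ()):
        self.records: list[EventRecord] = []
        for rec in records:
            self.append(rec)

    def append(self, record: EventRecord) -> None:
        if self.records and record.time_s < self.records[-1].time_s - 1e-9:
            raise EventLogError(
                f"event at t={record.time_s} appended after t={self.records[-1].time_s}"
            )
        self.records.append(record)

    def add(self, time_s: float, event: str, **kwargs) -> EventRecord:
        detail = kwargs.pop("detail", {})
        rec = EventRecord(time_s=time_s, event=event, detail=detail, **kwargs)
        self.append(rec)
        return rec

    def __iter__(self) -> Iterator[EventRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def of_kind(self, *kinds: str) -> list[EventRecord]:
        return [r for r in self.records if r.event in kinds]

    # -- CSV round trip ----------------------------------------------------

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(COLUMNS)
            for r in self.records:
                writer.writerow(
                    [
                        repr(float(r.time_s)),
                        r.event,
                        "" if r.actor is None else r.actor,
                        "" if r.bed is None else r.bed,
                        "" if r.request is None else r.request,
                        "" if r.level is None else r.level,
                        r.detail_str(),
                    ]
                )
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "EventLog":
        path = Path(path)
        log = cls()
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or tuple(header) != COLUMNS:
                raise EventLogError(f"{path}:1: unexpected header {header!r}")
            for lineno, row in enumerate(reader, start=2):
                if len(row) != len(COLUMNS):
                    raise EventLogError(f"{path}:{lineno}: expected {len(COLUMNS)} columns")
                try:
                    rec = EventRecord(
                        time_s=float(row[0]),
                        event=row[1],
                        actor=int(row[2]) if row[2] else None,
                        bed=int(row[3]) if row[3] else None,
                        request=int(row[4]) if row[4] else None,
                        level=int(row[5]) if row[5] else None,
                        detail=_parse_detail(row[6]),
                    )
                except (ValueError, EventLogError) as exc:
                    raise EventLogError(f"{path}:{lineno}: {exc}") from exc
                try:
                    log.append(rec)
                except EventLogError as exc:
                    raise EventLogError(f"{path}:{lineno}: {exc}") from exc
        return log
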