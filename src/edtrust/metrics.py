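"""Shift-level performance metrics, computed purely from the event log.

Five metric families, each at total and per-doctor / per-nurse granularity:

* **patients served** — completed tasks (one IV-catheter task per patient);
* **time damage** — sum of positive excesses of actual over doctor-requested
  execution duration, a patient-harm proxy;
* **total delay** — time patients sit with an issued but unclaimed request
  (travel to the bed counts as attended: the nurse is committed);
* **success/failure counts** — a task succeeds iff its actual execution time
  does not exceed the duration the doctor requested (non-strict), so a biased
  doctor distorts the labels;
* **utility** — per nurse, the sum of requested levels of successful tasks.

Because success is judged against the *requested* duration, an overestimating
doctor (shorter threshold) can fail a task that met the true gold standard,
and an underestimating doctor can pass one that missed it.  Doctor evaluation
accuracy is the fraction of requests whose requested level equals the true one.

The same function serves the live engine and the ``replay`` command: both feed
an event-record stream through :func:`metrics_from_log`, which is what makes
replayed metrics bit-identical to the run's own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import eventlog as ev
from .eventlog import EventLogError, EventRecord


def classify_success(actual_s: float, requested_duration_s: float) -> bool:
    """Success iff the actual execution time does not exceed the requested one."""
    if actual_s <= 0 or requested_duration_s <= 0:
        raise ValueError("durations must be positive")
    return actual_s <= requested_duration_s


def time_damage(actual_s: float, expected_s: float) -> float:
    """Positive excess of actual over expected duration (0 when on time)."""
    return max(0.0, actual_s - expected_s)


@dataclass
class ShiftMetrics:
    """Finalized metric families for one shift."""

    shift_length_s: float = 0.0
    patients_spawned: int = 0
    patients_served: int = 0
    served_by_doctor: dict[int, int] = field(default_factory=dict)
    time_damage_s: float = 0.0
    damage_by_nurse: dict[int, float] = field(default_factory=dict)
    damage_by_doctor: dict[int, float] = field(default_factory=dict)
    total_delay_s: float = 0.0
    delay_by_doctor: dict[int, float] = field(default_factory=dict)
    successes_by_nurse: dict[int, int] = field(default_factory=dict)
    failures_by_nurse: dict[int, int] = field(default_factory=dict)
    utility_by_nurse: dict[int, float] = field(default_factory=dict)
    requests_by_doctor: dict[int, int] = field(default_factory=dict)
    accurate_requests_by_doctor: dict[int, int] = field(default_factory=dict)
    nurse_info: dict[int, dict] = field(default_factory=dict)
    doctor_info: dict[int, dict] = field(default_factory=dict)

    def eval_accuracy(self, doctor_id: int) -> float:
        n = self.requests_by_doctor.get(doctor_id, 0)
        if n == 0:
            return math.nan
        return self.accurate_requests_by_doctor.get(doctor_id, 0) / n

    def tasks_by_nurse(self, nurse_id: int) -> int:
        return self.successes_by_nurse.get(nurse_id, 0) + self.failures_by_nurse.get(
            nurse_id, 0
        )

    def update_utility(self, nurse_id: int, requested_level: int, success: bool) -> None:
        """Tally one completed task: utility grows by the requested level on success."""
        if success:
            self.successes_by_nurse[nurse_id] = self.successes_by_nurse.get(nurse_id, 0) + 1
            self.utility_by_nurse[nurse_id] = (
                self.utility_by_nurse.get(nurse_id, 0.0) + requested_level
            )
        else:
            self.failures_by_nurse[nurse_id] = self.failures_by_nurse.get(nurse_id, 0) + 1
            self.utility_by_nurse.setdefault(nurse_id, 0.0)

    def accrue_time_damage(
        self, actual_s: float, expected_s: float, nurse_id: int, doctor_id: int
    ) -> None:
        """Add the positive deviation to the total, the nurse, and the doctor."""
        excess = time_damage(actual_s, expected_s)
        self.time_damage_s += excess
        self.damage_by_nurse[nurse_id] = self.damage_by_nurse.get(nurse_id, 0.0) + excess
        self.damage_by_doctor[doctor_id] = self.damage_by_doctor.get(doctor_id, 0.0) + excess

    def accrue_delay(self, wait_s: float, doctor_id: int) -> None:
        """Add one pure-waiting interval to the total and the owning doctor."""
        if wait_s < 0:
            raise ValueError("waiting intervals cannot be negative")
        self.total_delay_s += wait_s
        self.delay_by_doctor[doctor_id] = self.delay_by_doctor.get(doctor_id, 0.0) + wait_s


def metrics_from_log(records: Iterable[EventRecord]) -> ShiftMetrics:
    """Recompute all shift metrics from an ordered event stream.

    Validates the request life cycle (pending -> claimed -> completed) and
    raises :class:`EventLogError` at the first inconsistent transition, so a
    truncated or corrupted log fails loudly rather than producing bad numbers.
    """
    m = ShiftMetrics()
    status: dict[int, str] = {}
    issue: dict[int, EventRecord] = {}
    claim_time: dict[int, float] = {}
    end_time: float | None = None
    last_time = 0.0

    for i, rec in enumerate(records):
        if rec.time_s < last_time - 1e-9:
            raise EventLogError(f"record {i}: time goes backwards at t={rec.time_s}")
        last_time = rec.time_s
        kind = rec.event
        if kind == ev.DOCTOR_SPAWN:
            m.doctor_info[rec.actor] = dict(rec.detail)
            for d in (m.served_by_doctor, m.requests_by_doctor, m.accurate_requests_by_doctor):
                d.setdefault(rec.actor, 0)
            m.damage_by_doctor.setdefault(rec.actor, 0.0)
            m.delay_by_doctor.setdefault(rec.actor, 0.0)
        elif kind in (ev.NURSE_SPAWN, ev.REPLACEMENT_SPAWN):
            m.nurse_info[rec.actor] = dict(rec.detail)
            m.successes_by_nurse.setdefault(rec.actor, 0)
            m.failures_by_nurse.setdefault(rec.actor, 0)
            m.utility_by_nurse.setdefault(rec.actor, 0.0)
            m.damage_by_nurse.setdefault(rec.actor, 0.0)
        elif kind == ev.PATIENT_SPAWN:
            m.patients_spawned += 1
        elif kind == ev.REQUEST_ISSUED:
            if rec.request in status:
                raise EventLogError(f"record {i}: request {rec.request} issued twice")
            status[rec.request] = "pending"
            issue[rec.request] = rec
            doc = rec.actor
            m.requests_by_doctor[doc] = m.requests_by_doctor.get(doc, 0) + 1
            if rec.level == rec.detail.get("true_level"):
                m.accurate_requests_by_doctor[doc] = (
                    m.accurate_requests_by_doctor.get(doc, 0) + 1
                )
        elif kind == ev.CLAIM:
            if status.get(rec.request) != "pending":
                raise EventLogError(
                    f"record {i}: claim of request {rec.request} in state "
                    f"{status.get(rec.request)!r}"
                )
            status[rec.request] = "claimed"
            claim_time[rec.request] = rec.time_s
        elif kind == ev.TASK_COMPLETE:
            if status.get(rec.request) != "claimed":
                raise EventLogError(
                    f"record {i}: completion of request {rec.request} in state "
                    f"{status.get(rec.request)!r}"
                )
            status[rec.request] = "completed"
            nurse = rec.actor
            doctor = rec.detail["doctor"]
            actual = float(rec.detail["actual_duration_s"])
            requested = float(rec.detail["requested_duration_s"])
            success = classify_success(actual, requested)
            m.patients_served += 1
            m.served_by_doctor[doctor] = m.served_by_doctor.get(doctor, 0) + 1
            m.accrue_time_damage(actual, requested, nurse, doctor)
            m.update_utility(nurse, rec.level, success)
        elif kind == ev.SHIFT_END:
            end_time = rec.time_s

    if end_time is None:
        end_time = last_time
    m.shift_length_s = end_time

    # pure waiting: issue -> claim (or shift end if never claimed)
    for rid, rec in issue.items():
        until = claim_time.get(rid, end_time)
        m.accrue_delay(max(0.0, until - rec.time_s), rec.actor)
    return m


# ---------------------------------------------------------------------------
# CSV export


def run_row(metrics: ShiftMetrics, meta: Mapping) -> dict:
    """One wide row summarizing a run (totals only)."""
    return {
        "run_id": meta.get("run_id"),
        "scenario": meta.get("scenario"),
        "policy": meta.get("policy"),
        "seed": meta.get("seed"),
        "shift_length_s": metrics.shift_length_s,
        "patients_spawned": metrics.patients_spawned,
        "patients_served": metrics.patients_served,
        "total_delay_s": metrics.total_delay_s,
        "time_damage_s": metrics.time_damage_s,
        "tasks_completed": sum(
            metrics.tasks_by_nurse(n) for n in metrics.successes_by_nurse
        ),
        "successes": sum(metrics.successes_by_nurse.values()),
        "failures": sum(metrics.failures_by_nurse.values()),
    }


def doctor_rows(metrics: ShiftMetrics, meta: Mapping) -> list[dict]:
    rows = []
    for doc in sorted(metrics.requests_by_doctor):
        info = metrics.doctor_info.get(doc, {})
        rows.append(
            {
                "run_id": meta.get("run_id"),
                "doctor_id": doc,
                "style": info.get("style"),
                "patients_served": metrics.served_by_doctor.get(doc, 0),
                "time_damage_s": metrics.damage_by_doctor.get(doc, 0.0),
                "total_delay_s": metrics.delay_by_doctor.get(doc, 0.0),
                "requests_issued": metrics.requests_by_doctor.get(doc, 0),
                "eval_accuracy": metrics.eval_accuracy(doc),
            }
        )
    return rows


def nurse_rows(metrics: ShiftMetrics, meta: Mapping) -> list[dict]:
    rows = []
    for nurse in sorted(metrics.successes_by_nurse):
        info = metrics.nurse_info.get(nurse, {})
        rows.append(
            {
                "run_id": meta.get("run_id"),
                "nurse_id": nurse,
                "quality": info.get("quality"),
                "role": info.get("role"),
                "tasks_completed": metrics.tasks_by_nurse(nurse),
                "successes": metrics.successes_by_nurse.get(nurse, 0),
                "failures": metrics.failures_by_nurse.get(nurse, 0),
                "time_damage_s": metrics.damage_by_nurse.get(nurse, 0.0),
                "utility": metrics.utility_by_nurse.get(nurse, 0.0),
            }
        )
    return rows


def finalize_and_write(metrics: ShiftMetrics, meta: Mapping, outdir: str | Path) -> dict:
    """Write runs.csv / doctors.csv / nurses.csv for one run; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    try:
        for name, rows in (
            ("runs", [run_row(metrics, meta)]),
            ("doctors", doctor_rows(metrics, meta)),
            ("nurses", nurse_rows(metrics, meta)),
        ):
            path = outdir / f"{name}.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            paths[name] = path
    except OSError as exc:
        raise OSError(f"writing metrics for run {meta.get('run_id')!r}: {exc}") from exc
    return paths
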