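"""Event-driven shift simulation of the emergency room.

Logical topology only: nine beds in three doctor-owned blocks, a staff waiting
room, and a fixed per-leg travel time standing in for walking.  Patients are
spawned under saturated demand (a new patient the instant a bed frees) and
filled into beds along the fixed sequence 1,4,7,2,5,8,3,6,9 so that all three
doctors start examining as early as possible.  Each doctor examines (fixed
delay), then broadcasts one IV-catheter task request to every nurse; nurses
claim requests according to the configured policy (CA trust or FIFO), travel,
execute, and return to the waiting room.

Scenario hooks fire once per nurse when she self-assesses unreliable under CA:

* baseline — she restricts herself to low-difficulty tasks, no roster change;
* replacement — an additional high-performing nurse spawns in the waiting room
  and takes over the pending higher-difficulty requests;
* training — a trainer nurse spawns and mentors her; every mentored completion
  nudges her speed factor toward the high-quality value, and the trainer leaves
  once she reaches it.

The same (config, seed) pair always produces a bit-identical event log: the
event queue is ordered by (time, insertion sequence) and every agent draws from
its own seeded RNG substream, so roster changes never perturb other agents'
draws (common random numbers across scenarios).
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Optional

import numpy as np

from . import eventlog as ev
from .behavior import (
    LEVELS,
    DoctorProfile,
    LevelDurationMap,
    NurseProfile,
    TrainingState,
    apply_training_increment,
    evaluate_performance_level,
    get_task_duration,
    gold_duration,
)
from .config import (  # re-exported: the run configuration is part of the engine surface
    ConfigError,
    SimConfig,
    high_performer_profile,
    validate_config,
)
from .eventlog import EventLog
from .metrics import ShiftMetrics, classify_success, metrics_from_log
from .trust import (
    RequestStore,
    TrustState,
    record_outcome,
    select_request_ca,
    select_request_fifo,
    self_assess,
)

__all__ = [
    "TaskRequest",
    "BedMap",
    "Simulation",
    "run_shift",
    "SimConfig",
    "ConfigError",
]

_RNG_KIND = {"doctor": 1, "nurse": 2}


def agent_rng(master_seed: int, kind: str, agent_id: int) -> np.random.Generator:
    """Independent, reproducible RNG substream for one agent."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(_RNG_KIND[kind], agent_id))
    return np.random.default_rng(ss)


@dataclass
class TaskRequest:
    """One doctor-issued nursing task (IV-catheter insertion)."""

    request_id: int
    patient_id: int
    bed_id: int
    doctor_id: int
    true_level: int
    requested_level: int
    requested_duration_s: float
    issue_time_s: float
    status: str = "pending"  # pending -> claimed -> completed
    nurse_id: Optional[int] = None
    claim_time_s: Optional[float] = None
    actual_duration_s: Optional[float] = None
    completion_time_s: Optional[float] = None


class BedMap:
    """Bed occupancy with the fixed initial-fill sequence, then oldest-freed first."""

    def __init__(self, fill_order: tuple[int, ...], owner: dict[int, int]):
        self.fill_order = tuple(fill_order)
        self.owner = dict(owner)
        self.occupancy: dict[int, Optional[int]] = {b: None for b in fill_order}
        self._fill_idx = 0
        self._freed: deque[int] = deque()

    def next_bed(self) -> Optional[int]:
        """Next bed a new patient should take, or None if all are occupied."""
        while self._fill_idx < len(self.fill_order):
            bed = self.fill_order[self._fill_idx]
            if self.occupancy[bed] is None:
                return bed
            self._fill_idx += 1  # pragma: no cover - defensive, occupy() advances
        if self._freed:
            return self._freed[0]
        return None

    def occupy(self, bed: int, patient_id: int) -> None:
        if self.occupancy[bed] is not None:
            raise RuntimeError(f"bed {bed} already occupied")
        if self._fill_idx < len(self.fill_order) and bed == self.fill_order[self._fill_idx]:
            self._fill_idx += 1
        elif self._freed and bed == self._freed[0]:
            self._freed.popleft()
        else:
            raise RuntimeError(f"bed {bed} is not the next bed in sequence")
        self.occupancy[bed] = patient_id

    def release(self, bed: int) -> None:
        if self.occupancy[bed] is None:
            raise RuntimeError(f"bed {bed} is already empty")
        self.occupancy[bed] = None
        self._freed.append(bed)

    def occupied_count(self) -> int:
        return sum(1 for p in self.occupancy.values() if p is not None)


@dataclass
class _DoctorState:
    profile: DoctorProfile
    rng: np.random.Generator
    busy: bool = False
    exam_queue: deque = field(default_factory=deque)  # (bed, patient_id)


@dataclass
class _NurseState:
    profile: NurseProfile
    rng: Optional[np.random.Generator]
    store: RequestStore = field(default_factory=RequestStore)
    trust: Optional[TrustState] = None
    training: Optional[TrainingState] = None
    idle: bool = True
    hook_fired: bool = False
    trainer_id: Optional[int] = None


class Simulation:
    """One shift, driven by a (time, sequence)-ordered event queue."""

    def __init__(self, config: SimConfig):
        self.config = validate_config(config)
        self.dmap: LevelDurationMap = config.duration_map
        self.log = EventLog()
        self.clock = 0.0
        self._heap: list[tuple[float, int, str, tuple]] = []
        self._seq = 0
        self._patient_counter = 0
        self.requests: dict[int, TaskRequest] = {}
        self._level_values = np.array(LEVELS)
        self._level_probs = np.array(
            [config.level_probabilities[lvl] for lvl in LEVELS]
        )

        owner = {}
        for doc in config.doctors:
            for bed in doc.assigned_beds:
                owner[bed] = doc.doctor_id
        self.beds = BedMap(config.bed_fill_order, owner)

        self.doctors: dict[int, _DoctorState] = {}
        for doc in config.doctors:
            self.doctors[doc.doctor_id] = _DoctorState(
                profile=doc, rng=agent_rng(config.seed, "doctor", doc.doctor_id)
            )
        self.nurses: dict[int, _NurseState] = {}
        for nurse in config.nurses:
            # work on a copy: training mutates speed_factor, and the caller's
            # config (e.g. a batch template) must stay pristine across runs
            self._add_nurse(_dc_replace(nurse), time_s=0.0, kind=ev.NURSE_SPAWN)

    # -- roster ------------------------------------------------------------

    def _add_nurse(self, profile: NurseProfile, time_s: float, kind: str) -> _NurseState:
        state = _NurseState(
            profile=profile,
            rng=agent_rng(self.config.seed, "nurse", profile.nurse_id),
        )
        if self.config.policy == "ca" and profile.role != "trainer":
            tc = self.config.trust
            state.trust = TrustState(
                weights={lvl: tc.initial_weight for lvl in LEVELS},
                attempts={lvl: 0 for lvl in LEVELS},
            )
        if profile.role != "trainer":
            # a nurse spawned mid-shift sees every still-pending broadcast request
            for req in sorted(
                (r for r in self.requests.values() if r.status == "pending"),
                key=lambda r: (r.issue_time_s, r.request_id),
            ):
                state.store.add(req.request_id)
        self.nurses[profile.nurse_id] = state
        self.log.add(
            time_s,
            kind,
            actor=profile.nurse_id,
            detail={"quality": profile.quality, "role": profile.role},
        )
        return state

    def _next_nurse_id(self) -> int:
        return max(self.nurses) + 1 if self.nurses else 1

    # -- event queue -------------------------------------------------------

    def _schedule(self, time_s: float, kind: str, *args) -> None:
        heapq.heappush(self._heap, (time_s, self._seq, kind, args))
        self._seq += 1

    # -- patients & doctors ------------------------------------------------

    def _spawn_patients(self, t: float) -> None:
        """Saturated demand: fill every available bed immediately."""
        while (bed := self.beds.next_bed()) is not None:
            self._patient_counter += 1
            pid = self._patient_counter
            self.beds.occupy(bed, pid)
            self.log.add(t, ev.PATIENT_SPAWN, actor=pid, bed=bed)
            doctor = self.doctors[self.beds.owner[bed]]
            doctor.exam_queue.append((bed, pid))
            self._maybe_start_exam(doctor, t)

    def _maybe_start_exam(self, doctor: _DoctorState, t: float) -> None:
        if doctor.busy or not doctor.exam_queue:
            return
        bed, pid = doctor.exam_queue.popleft()
        doctor.busy = True
        self.log.add(t, ev.EXAM_START, actor=doctor.profile.doctor_id, bed=bed)
        self._schedule(t + doctor.profile.exam_duration_s, "exam_done", doctor.profile.doctor_id, bed, pid)

    def examine_patient(self, doctor_id: int, bed: int, patient_id: int, t: float) -> TaskRequest:
        """Finish an examination: create and broadcast one task request."""
        doctor = self.doctors[doctor_id]
        true_level = int(doctor.rng.choice(self._level_values, p=self._level_probs))
        requested = evaluate_performance_level(true_level, doctor.profile)
        req = TaskRequest(
            request_id=len(self.requests) + 1,
            patient_id=patient_id,
            bed_id=bed,
            doctor_id=doctor_id,
            true_level=true_level,
            requested_level=requested,
            requested_duration_s=gold_duration(requested, self.dmap),
            issue_time_s=t,
        )
        self.requests[req.request_id] = req
        self.log.add(
            t,
            ev.REQUEST_ISSUED,
            actor=doctor_id,
            bed=bed,
            request=req.request_id,
            level=requested,
            detail={
                "true_level": true_level,
                "requested_duration_s": req.requested_duration_s,
                "patient": patient_id,
            },
        )
        for nurse in self.nurses.values():
            if nurse.profile.role != "trainer":
                nurse.store.add(req.request_id)
        doctor.busy = False
        self._maybe_start_exam(doctor, t)
        return req

    # -- nurses ------------------------------------------------------------

    def _dispatch(self, t: float) -> None:
        """Let idle nurses claim eligible requests, lowest nurse id first."""
        for nid in sorted(self.nurses):
            nurse = self.nurses[nid]
            if not nurse.idle or nurse.profile.role == "trainer":
                continue
            if self.config.policy == "fifo":
                req = select_request_fifo(nurse.store, self.requests)
            else:
                req = select_request_ca(nurse.trust, nurse.store, self.requests)
            if req is not None:
                self._claim(nurse, req, t)

    def _claim(self, nurse: _NurseState, req: TaskRequest, t: float) -> None:
        req.status = "claimed"
        req.nurse_id = nurse.profile.nurse_id
        req.claim_time_s = t
        for other in self.nurses.values():
            other.store.discard(req.request_id)
        detail: dict = {}
        if nurse.trust is not None:
            detail = {f"w{lvl}": nurse.trust.weights[lvl] for lvl in LEVELS}
        self.log.add(
            t,
            ev.CLAIM,
            actor=nurse.profile.nurse_id,
            bed=req.bed_id,
            request=req.request_id,
            level=req.requested_level,
            detail=detail,
        )
        nurse.idle = False
        self._schedule(t + self.config.travel_time_s, "arrive", nurse.profile.nurse_id, req.request_id)

    def _on_arrive(self, nurse_id: int, request_id: int, t: float) -> None:
        nurse = self.nurses[nurse_id]
        req = self.requests[request_id]
        if req.status == "completed":  # another nurse got here first
            self.log.add(t, ev.ABANDON, actor=nurse_id, bed=req.bed_id, request=request_id)
            self._schedule(t + self.config.travel_time_s, "home", nurse_id)
            return
        self.log.add(t, ev.ARRIVE, actor=nurse_id, bed=req.bed_id, request=request_id)
        draw = None
        if self.config.noise_enabled:
            u = float(nurse.rng.random())
            while not 0.0 < u < 1.0:  # pragma: no cover - measure-zero redraw
                u = float(nurse.rng.random())
            draw = u
        duration = get_task_duration(
            nurse.profile, nurse.training, req.true_level, draw, self.dmap
        )
        self.log.add(
            t,
            ev.EXECUTE_START,
            actor=nurse_id,
            bed=req.bed_id,
            request=request_id,
            level=req.requested_level,
            detail={"duration_s": duration},
        )
        self._schedule(t + duration, "task_done", nurse_id, request_id, duration)

    def execute_task(self, nurse_id: int, request_id: int, duration: float, t: float) -> None:
        """Complete a task: metrics log, trust and training updates, bed turnover."""
        nurse = self.nurses[nurse_id]
        req = self.requests[request_id]
        req.status = "completed"
        req.actual_duration_s = duration
        req.completion_time_s = t
        success = classify_success(duration, req.requested_duration_s)
        self.log.add(
            t,
            ev.TASK_COMPLETE,
            actor=nurse_id,
            bed=req.bed_id,
            request=request_id,
            level=req.requested_level,
            detail={
                "doctor": req.doctor_id,
                "patient": req.patient_id,
                "true_level": req.true_level,
                "requested_duration_s": req.requested_duration_s,
                "actual_duration_s": duration,
                "success": success,
            },
        )
        self._apply_feedback(nurse, req, success, t)
        # patient served: free the bed, saturated demand refills it immediately
        self.beds.release(req.bed_id)
        self._spawn_patients(t)
        self._schedule(t + self.config.travel_time_s, "home", nurse_id)

    def _apply_feedback(self, nurse: _NurseState, req: TaskRequest, success: bool, t: float) -> None:
        if nurse.training is not None and nurse.training.active:
            apply_training_increment(nurse.training, nurse.profile)
            self.log.add(
                t,
                ev.TRAINING_PROGRESS,
                actor=nurse.profile.nurse_id,
                detail={
                    "observed_count": nurse.training.observed_count,
                    "speed_factor": nurse.profile.speed_factor,
                },
            )
            if not nurse.training.active:
                self._finish_training(nurse, t)
        if nurse.trust is None:
            return
        record_outcome(
            nurse.trust, req.requested_level, success, self.config.trust.learning_rate
        )
        was_reliable = nurse.trust.reliable
        old_cap = nurse.trust.restricted_max_level
        cap = (
            self.config.trust.baseline_cap
            if self.config.scenario in ("baseline", "replacement")
            else None
        )
        self_assess(
            nurse.trust,
            self.config.trust.threshold,
            self.config.trust.min_attempts,
            cap=cap,
        )
        if nurse.trust.reliable:
            return
        if was_reliable or nurse.trust.restricted_max_level != old_cap:
            self.log.add(
                t,
                ev.SELF_ASSESS_UNRELIABLE,
                actor=nurse.profile.nurse_id,
                detail={"restricted_max_level": nurse.trust.restricted_max_level}
                if nurse.trust.restricted_max_level is not None
                else {},
            )
        if was_reliable and not nurse.hook_fired:
            nurse.hook_fired = True
            self.scenario_on_unreliable(nurse, t)

    def scenario_on_unreliable(self, nurse: _NurseState, t: float) -> None:
        """Managerial response to a freshly self-assessed low performer."""
        if self.config.policy != "ca":
            raise RuntimeError("scenario hooks require the CA policy (FIFO never self-assesses)")
        scenario = self.config.scenario
        if scenario == "baseline":
            return  # restriction already applied; no extra staff
        if scenario == "replacement":
            profile = high_performer_profile(self._next_nurse_id())
            self._add_nurse(profile, t, ev.REPLACEMENT_SPAWN)
            return
        # training: spawn a mentor and activate the learning process
        tc = self.config.training
        trainer = NurseProfile(
            self._next_nurse_id(), "high", 0.9, 0.0, role="trainer"
        )
        trainer_state = _NurseState(profile=trainer, rng=None, idle=False)
        self.nurses[trainer.nurse_id] = trainer_state
        nurse.trainer_id = trainer.nurse_id
        self.log.add(
            t, ev.TRAINER_SPAWN, actor=trainer.nurse_id, detail={"trainee": nurse.profile.nurse_id}
        )
        nurse.training = TrainingState(
            active=True,
            completion_threshold=tc.completion_threshold,
            decrement=tc.decrement,
            floor=tc.floor,
        )
        if nurse.profile.speed_factor <= tc.completion_threshold:
            nurse.training.active = False
            self._finish_training(nurse, t)

    def _finish_training(self, nurse: _NurseState, t: float) -> None:
        """Mentoring complete: the trainer leaves, the nurse resumes fully."""
        if nurse.trainer_id is not None:
            self.log.add(
                t, ev.TRAINER_EXIT, actor=nurse.trainer_id,
                detail={"trainee": nurse.profile.nurse_id},
            )
            self.nurses.pop(nurse.trainer_id, None)
            nurse.trainer_id = None
        if nurse.trust is not None:
            nurse.trust.reliable = True
            nurse.trust.restricted_max_level = None

    # -- main loop ---------------------------------------------------------

    def run(self) -> tuple[ShiftMetrics, EventLog]:
        end = self.config.shift_length_s
        for doc in self.config.doctors:
            self.log.add(0.0, ev.DOCTOR_SPAWN, actor=doc.doctor_id, detail={"style": doc.style})
        self._spawn_patients(0.0)
        self._dispatch(0.0)
        while self._heap and self._heap[0][0] <= end:
            t, _, kind, args = heapq.heappop(self._heap)
            self.clock = t
            if kind == "exam_done":
                self.examine_patient(*args, t)
            elif kind == "arrive":
                self._on_arrive(*args, t)
            elif kind == "task_done":
                self.execute_task(*args, t)
            elif kind == "home":
                self.nurses[args[0]].idle = True
            self._dispatch(t)
        self.log.add(end, ev.SHIFT_END)
        return metrics_from_log(self.log.records), self.log


def run_shift(config: SimConfig) -> tuple[ShiftMetrics, EventLog]:
    """Simulate one shift; identical (config, seed) gives bit-identical output."""
    return Simulation(config).run()
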