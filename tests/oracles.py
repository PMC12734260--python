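"""Independent oracles for cross-checking the event-queue engine.

``timestep_shift`` advances a noise-free shift in fixed 1-second ticks with
explicit per-tick state machines — no event queue — and returns the aggregate
quantities the engine must reproduce.  It shares only the agent primitives
(duration/evaluation rules, trust arithmetic) and the seed derivation with the
package; the scheduling control flow is written from scratch.

Within a tick the processing order mirrors what physical causality forces on
any scheduler here: task completions were begun longest ago, examinations
started 10 s ago, and travel legs 5 s ago, so completions resolve first, then
exams (issuing requests), then already-idle nurses claim, then arrivals start
executing, then returning nurses go idle and claim in the order they finished.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from edtrust.behavior import (
    LEVELS,
    evaluate_performance_level,
    get_task_duration,
    gold_duration,
)
from edtrust.config import SimConfig
from edtrust.engine import agent_rng
from edtrust.trust import TrustState, record_outcome, self_assess

import numpy as np


@dataclass
class OracleResult:
    patients_served: int = 0
    completion_times: list[float] = field(default_factory=list)
    tasks_by_nurse: dict[int, int] = field(default_factory=dict)
    time_damage_s: float = 0.0
    total_delay_s: float = 0.0
    patients_spawned: int = 0


@dataclass
class _Req:
    rid: int
    bed: int
    doctor: int
    true_level: int
    requested_level: int
    requested_duration: float
    issue_t: int
    claim_t: int | None = None
    done: bool = False


def timestep_shift(config: SimConfig, dt: int = 1) -> OracleResult:
    assert not config.noise_enabled, "oracle only covers the deterministic mode"
    shift = int(config.shift_length_s)
    travel = config.travel_time_s
    res = OracleResult()

    level_values = np.array(LEVELS)
    level_probs = np.array([config.level_probabilities[lvl] for lvl in LEVELS])
    doc_rng = {d.doctor_id: agent_rng(config.seed, "doctor", d.doctor_id) for d in config.doctors}
    doc_by_id = {d.doctor_id: d for d in config.doctors}
    owner = {b: d.doctor_id for d in config.doctors for b in d.assigned_beds}

    # beds
    fill = list(config.bed_fill_order)
    fill_idx = 0
    freed: deque[int] = deque()
    occupied: dict[int, bool] = {b: False for b in fill}

    # doctors: (end_t, bed, patient) or None; queue of (bed, patient)
    exam: dict[int, tuple[int, int, int] | None] = {d: None for d in doc_by_id}
    exam_q: dict[int, deque] = {d: deque() for d in doc_by_id}

    # nurses: phase in {idle, to_bed, exec, to_home}; timer end; current req
    nurses = {n.nurse_id: n for n in config.nurses if n.role != "trainer"}
    phase = {nid: "idle" for nid in nurses}
    timer_end: dict[int, int] = {}
    current: dict[int, _Req] = {}
    home_order: deque[int] = deque()  # nurses whose return leg ends, completion order
    trust: dict[int, TrustState] = {}
    if config.policy == "ca":
        for nid in nurses:
            trust[nid] = TrustState(
                weights={lvl: config.trust.initial_weight for lvl in LEVELS},
                attempts={lvl: 0 for lvl in LEVELS},
            )
    res.tasks_by_nurse = {nid: 0 for nid in nurses}

    requests: list[_Req] = []
    pending: list[_Req] = []
    exec_order: dict[int, int] = {}  # nurse -> sequence number of execution start
    exec_seq = 0
    home_seq: dict[int, int] = {}  # nurse -> order in which the return leg began
    next_home_seq = 0
    patient_count = 0

    def spawn_patients(t: int) -> None:
        nonlocal fill_idx, patient_count
        while True:
            if fill_idx < len(fill):
                bed = fill[fill_idx]
                fill_idx += 1
            elif freed:
                bed = freed.popleft()
            else:
                return
            patient_count += 1
            occupied[bed] = True
            res.patients_spawned += 1
            exam_q[owner[bed]].append((bed, patient_count))
            start_exam(owner[bed], t)

    def start_exam(did: int, t: int) -> None:
        if exam[did] is None and exam_q[did]:
            bed, pid = exam_q[did].popleft()
            exam[did] = (t + int(doc_by_id[did].exam_duration_s), bed, pid)

    def eligible(nid: int, req: _Req) -> bool:
        if config.policy == "fifo":
            return True
        return trust[nid].accepts_level(req.requested_level)

    def try_claim(nid: int, t: int) -> None:
        nonlocal exec_seq
        for req in sorted(pending, key=lambda r: (r.issue_t, r.rid)):
            if eligible(nid, req):
                pending.remove(req)
                req.claim_t = t
                phase[nid] = "to_bed"
                timer_end[nid] = t + int(travel)
                current[nid] = req
                return

    spawn_patients(0)
    for nid in sorted(nurses):
        try_claim(nid, 0)

    for t in range(dt, shift + 1, dt):
        # 1. completions (ordered by execution start)
        done_now = sorted(
            (nid for nid in nurses if phase[nid] == "exec" and timer_end[nid] == t),
            key=lambda nid: exec_order[nid],
        )
        for nid in done_now:
            req = current.pop(nid)
            req.done = True
            nurse = nurses[nid]
            actual = get_task_duration(nurse, None, req.true_level, None, config.duration_map)
            res.patients_served += 1
            res.completion_times.append(float(t))
            res.tasks_by_nurse[nid] += 1
            res.time_damage_s += max(0.0, actual - req.requested_duration)
            if config.policy == "ca":
                success = actual <= req.requested_duration
                record_outcome(trust[nid], req.requested_level, success, config.trust.learning_rate)
                cap = config.trust.baseline_cap if config.scenario in ("baseline", "replacement") else None
                self_assess(trust[nid], config.trust.threshold, config.trust.min_attempts, cap=cap)
            occupied[req.bed] = False
            freed.append(req.bed)
            spawn_patients(t)
            phase[nid] = "to_home"
            timer_end[nid] = t + int(travel)
            home_seq[nid] = next_home_seq
            next_home_seq += 1
        # 2. exam completions -> broadcast requests
        for did in sorted(exam, key=lambda d: (exam[d][0], d) if exam[d] else (shift + 2, d)):
            if exam[did] is not None and exam[did][0] == t:
                _, bed, pid = exam[did]
                true_level = int(doc_rng[did].choice(level_values, p=level_probs))
                requested = evaluate_performance_level(true_level, doc_by_id[did])
                req = _Req(
                    rid=len(requests) + 1,
                    bed=bed,
                    doctor=did,
                    true_level=true_level,
                    requested_level=requested,
                    requested_duration=gold_duration(requested, config.duration_map),
                    issue_t=t,
                )
                requests.append(req)
                pending.append(req)
                exam[did] = None
                start_exam(did, t)
        # 3. nurses idle from before this tick claim (lowest id first)
        for nid in sorted(nurses):
            if phase[nid] == "idle":
                try_claim(nid, t)
        # 4. arrivals begin execution
        for nid in sorted(nurses):
            if phase[nid] == "to_bed" and timer_end[nid] == t:
                req = current[nid]
                actual = get_task_duration(
                    nurses[nid], None, req.true_level, None, config.duration_map
                )
                phase[nid] = "exec"
                timer_end[nid] = t + int(actual)
                exec_order[nid] = exec_seq
                exec_seq += 1
        # 5. returning nurses go idle and claim, in the order they set off home
        for nid in sorted(nurses, key=lambda n: home_seq.get(n, 0)):
            if phase[nid] == "to_home" and timer_end[nid] == t:
                phase[nid] = "idle"
                try_claim(nid, t)

    # pure waiting time: issue -> claim (or shift end)
    for req in requests:
        until = req.claim_t if req.claim_t is not None else shift
        res.total_delay_s += max(0.0, float(until - req.issue_t))
    res.completion_times.sort()
    return res


def fifo_brute_force(issue_times: list[float]) -> list[int]:
    """Expected FIFO service order (indices) for one nurse: by issue time, then id."""
    return sorted(range(len(issue_times)), key=lambda i: (issue_times[i], i))


def trust_closed_form(w0: float, alpha: float, n: int, success: bool) -> float:
    """Weight after n identical outcomes: geometric approach to 1 (or 0)."""
    if success:
        return 1.0 - (1.0 - w0) * (1.0 - alpha) ** n
    return w0 * (1.0 - alpha) ** n
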