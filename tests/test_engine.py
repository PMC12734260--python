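"""Shift mechanics: bed sequence, scheduling arithmetic, scenarios, determinism."""

import math
from dataclasses import replace

import pytest

from edtrust import eventlog as ev
from edtrust.behavior import DoctorProfile, NurseProfile
from edtrust.config import ConfigError, SimConfig, validate_config
from edtrust.engine import BedMap, Simulation, run_shift

from oracles import timestep_shift


def test_bed_map_initial_fill_then_freed_order():
    owner = {b: 1 for b in range(1, 10)}
    beds = BedMap((1, 4, 7, 2, 5, 8, 3, 6, 9), owner)
    assert beds.next_bed() == 1
    beds.occupy(1, 101)
    assert beds.next_bed() == 4
    for b in (4, 7, 2, 5, 8, 3, 6, 9):
        beds.occupy(b, 100 + b)
    assert beds.next_bed() is None
    beds.release(6)
    beds.release(2)
    assert beds.next_bed() == 6  # oldest freed first
    beds.occupy(6, 201)
    assert beds.next_bed() == 2


def test_saturated_shift_fills_beds_in_fixed_sequence():
    _, log = run_shift(SimConfig(scenario="baseline", policy="fifo", seed=3))
    spawned_beds = [r.bed for r in log.of_kind(ev.PATIENT_SPAWN)][:9]
    assert spawned_beds == [1, 4, 7, 2, 5, 8, 3, 6, 9]


def test_exam_delay_and_broadcast(tiny_config):
    _, log = run_shift(tiny_config)
    first_exam = log.of_kind(ev.EXAM_START)[0]
    first_req = log.of_kind(ev.REQUEST_ISSUED)[0]
    assert first_exam.time_s == 0.0
    assert first_req.time_s == 10.0  # fixed 10 s examination
    # the doctor serializes exams over their own beds
    issue_times = [r.time_s for r in log.of_kind(ev.REQUEST_ISSUED)[:3]]
    assert issue_times == [10.0, 20.0, 30.0]


def test_claim_travel_execute_arithmetic(tiny_config):
    """claim + travel 5 s + execution = completion; return leg precedes next claim."""
    _, log = run_shift(tiny_config)
    claims = {r.request: r for r in log.of_kind(ev.CLAIM)}
    for done in log.of_kind(ev.TASK_COMPLETE)[:5]:
        claim = claims[done.request]
        start = next(
            r for r in log.of_kind(ev.EXECUTE_START) if r.request == done.request
        )
        assert start.time_s == claim.time_s + tiny_config.travel_time_s
        assert done.time_s == pytest.approx(start.time_s + done.detail["actual_duration_s"])


def test_same_seed_bit_identical():
    config = SimConfig(scenario="training", policy="ca", seed=11, shift_length_s=4000.0)
    m1, log1 = run_shift(config)
    m2, log2 = run_shift(SimConfig(scenario="training", policy="ca", seed=11, shift_length_s=4000.0))
    assert log1.records == log2.records
    assert m1 == m2


def test_zero_nurses_degenerate():
    config = SimConfig(
        scenario="baseline", policy="fifo", seed=0, shift_length_s=500.0, nurses=[]
    )
    metrics, log = run_shift(config)
    assert metrics.patients_served == 0
    assert metrics.patients_spawned == 9
    # every issued request waits, unattended, until shift end
    issued = log.of_kind(ev.REQUEST_ISSUED)
    expected = sum(500.0 - r.time_s for r in issued)
    assert metrics.total_delay_s == pytest.approx(expected)


def test_single_server_closed_form_throughput(single_server_config):
    """1 doctor / 1 bed / 1 high nurse, level 3, noise off: one patient per 51 s."""
    cycle = 10.0 + 5.0 + 0.9 * 40.0  # exam + travel + execution; return overlaps exam
    metrics, log = run_shift(single_server_config)
    assert metrics.patients_served == math.floor(single_server_config.shift_length_s / cycle)
    completions = [r.time_s for r in log.of_kind(ev.TASK_COMPLETE)]
    assert completions == [cycle * (k + 1) for k in range(len(completions))]


def test_conservation_and_no_double_use():
    for combo in (("baseline", "fifo"), ("baseline", "ca"), ("replacement", "ca")):
        config = SimConfig(scenario=combo[0], policy=combo[1], seed=5, shift_length_s=6000.0)
        metrics, log = run_shift(config)
        # spawned = served + still in a bed at shift end
        in_beds = metrics.patients_spawned - metrics.patients_served
        assert 0 <= in_beds <= config.n_beds
        # no request claimed or completed twice; beds never double-booked
        seen_claim, seen_done, bed_state = set(), set(), {}
        for rec in log:
            if rec.event == ev.PATIENT_SPAWN:
                assert bed_state.get(rec.bed) is None
                bed_state[rec.bed] = rec.actor
            elif rec.event == ev.TASK_COMPLETE:
                assert rec.request not in seen_done
                seen_done.add(rec.request)
                bed_state[rec.bed] = None
            elif rec.event == ev.CLAIM:
                assert rec.request not in seen_claim
                seen_claim.add(rec.request)
        assert seen_done <= seen_claim


def test_all_high_noise_off_zero_damage():
    """Correct doctors + high performers + no noise: every task succeeds, no damage."""
    config = SimConfig(
        scenario="baseline",
        policy="fifo",
        seed=2,
        shift_length_s=3000.0,
        nurses=[NurseProfile(1, "high", 0.9, 0.1), NurseProfile(2, "high", 0.9, 0.1)],
        noise_enabled=False,
    )
    metrics, _ = run_shift(config)
    assert metrics.time_damage_s == 0.0
    assert sum(metrics.failures_by_nurse.values()) == 0
    assert metrics.patients_served > 0


def test_fifo_outside_baseline_rejected():
    with pytest.raises(ConfigError):
        validate_config(SimConfig(scenario="training", policy="fifo"))
    with pytest.raises(ConfigError):
        validate_config(SimConfig(scenario="replacement", policy="fifo"))


def test_replacement_spawns_one_high_performer():
    config = SimConfig(scenario="replacement", policy="ca", seed=1, shift_length_s=10_000.0)
    metrics, log = run_shift(config)
    spawns = log.of_kind(ev.REPLACEMENT_SPAWN)
    assert len(spawns) >= 1
    first = spawns[0]
    assert first.detail["quality"] == "high"
    # the replacement fires only after a self-assessment, and claims pending work
    first_sa = log.of_kind(ev.SELF_ASSESS_UNRELIABLE)[0]
    assert first.time_s >= first_sa.time_s
    claims_after = [
        r for r in log.of_kind(ev.CLAIM) if r.actor == first.actor
    ]
    assert claims_after, "replacement nurse must take over pending requests"


def test_training_spawns_trainer_who_never_executes_and_leaves():
    config = SimConfig(scenario="training", policy="ca", seed=1)
    metrics, log = run_shift(config)
    trainer = log.of_kind(ev.TRAINER_SPAWN)[0]
    trainee = trainer.detail["trainee"]
    assert all(r.actor != trainer.actor for r in log.of_kind(ev.EXECUTE_START))
    progress = [r for r in log.of_kind(ev.TRAINING_PROGRESS) if r.actor == trainee]
    factors = [r.detail["speed_factor"] for r in progress]
    assert factors == sorted(factors, reverse=True)  # non-increasing skill curve
    exits = log.of_kind(ev.TRAINER_EXIT)
    if exits:  # mentoring finished within the shift
        assert factors[-1] == pytest.approx(config.training.floor)


def test_unreliable_nurse_never_claims_above_cap():
    config = SimConfig(scenario="baseline", policy="ca", seed=9)
    _, log = run_shift(config)
    cap_at = {}  # nurse -> (time, cap) timeline
    for rec in log:
        if rec.event == ev.SELF_ASSESS_UNRELIABLE:
            cap_at.setdefault(rec.actor, []).append(
                (rec.time_s, rec.detail.get("restricted_max_level"))
            )
        elif rec.event == ev.CLAIM and rec.actor in cap_at:
            current_cap = [c for t, c in cap_at[rec.actor] if t <= rec.time_s][-1]
            if current_cap is not None:
                assert rec.level <= current_cap


def test_ca_prefix_equivalence_baseline_vs_replacement():
    """Common random numbers + noise off: identical logs up to the first self-assessment."""
    base = SimConfig(scenario="baseline", policy="ca", seed=4, shift_length_s=8000.0,
                     noise_enabled=False)
    repl = replace(base, scenario="replacement")
    _, log_b = run_shift(base)
    _, log_r = run_shift(repl)
    sa_idx = next(
        i for i, r in enumerate(log_b.records) if r.event == ev.SELF_ASSESS_UNRELIABLE
    )
    assert log_b.records[: sa_idx + 1] == log_r.records[: sa_idx + 1]


@pytest.mark.parametrize("policy", ["fifo", "ca"])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_engine_matches_timestep_oracle(tiny_config, policy, seed):
    """The event queue agrees with a 1 s time-stepping simulation of the same shift."""
    config = replace(tiny_config, policy=policy, seed=seed)
    metrics, log = run_shift(config)
    oracle = timestep_shift(config)
    assert metrics.patients_served == oracle.patients_served
    assert metrics.patients_spawned == oracle.patients_spawned
    completions = sorted(r.time_s for r in log.of_kind(ev.TASK_COMPLETE))
    assert completions == pytest.approx(oracle.completion_times)
    for nid, count in oracle.tasks_by_nurse.items():
        assert metrics.tasks_by_nurse(nid) == count
    assert metrics.time_damage_s == pytest.approx(oracle.time_damage_s)
    assert metrics.total_delay_s == pytest.approx(oracle.total_delay_s)


def test_nurse_relabeling_leaves_damage_and_delay_invariant():
    """Noise off: renaming a nurse's id only re-keys her per-nurse metrics."""
    a = SimConfig(
        scenario="baseline", policy="fifo", seed=0, shift_length_s=3000.0,
        nurses=[NurseProfile(1, "low", 1.5, 0.25)], noise_enabled=False,
    )
    b = replace(a, nurses=[NurseProfile(7, "low", 1.5, 0.25)])
    ma, _ = run_shift(a)
    mb, _ = run_shift(b)
    assert ma.time_damage_s == pytest.approx(mb.time_damage_s)
    assert ma.total_delay_s == pytest.approx(mb.total_delay_s)
    assert ma.patients_served == mb.patients_served
    assert ma.damage_by_nurse[1] == pytest.approx(mb.damage_by_nurse[7])
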