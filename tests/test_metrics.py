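"""Success labeling, damage/delay/utility accounting, CSV export, replay."""

import math

import pytest

from edtrust import eventlog as ev
from edtrust.config import SimConfig
from edtrust.behavior import DoctorProfile
from edtrust.engine import run_shift
from edtrust.eventlog import EventLog, EventLogError, EventRecord
from edtrust.metrics import (
    ShiftMetrics,
    classify_success,
    finalize_and_write,
    metrics_from_log,
    time_damage,
)


@pytest.mark.parametrize(
    "actual,requested,expected",
    [
        (30.0, 20.0, False),  # overestimated to level 5: 30 s misses the 20 s bar
        (30.0, 40.0, True),   # the same 30 s passes the true level-3 bar of 40 s
        (20.0, 20.0, True),   # "does not exceed" is non-strict
    ],
)
def test_success_labeling_follows_requested_duration(actual, requested, expected):
    assert classify_success(actual, requested) is expected


def test_time_damage_positive_part_only():
    assert time_damage(30.0, 20.0) == 10.0
    assert time_damage(18.0, 20.0) == 0.0


def test_damage_accrues_to_all_three_sinks_and_adds_up():
    m = ShiftMetrics()
    m.accrue_time_damage(30.0, 20.0, nurse_id=2, doctor_id=1)
    m.accrue_time_damage(25.0, 20.0, nurse_id=2, doctor_id=1)
    assert m.time_damage_s == 15.0
    assert m.damage_by_nurse[2] == 15.0
    assert m.damage_by_doctor[1] == 15.0


def test_delay_interval_additivity():
    m = ShiftMetrics()
    m.accrue_delay(5.0, doctor_id=1)
    m.accrue_delay(7.0, doctor_id=1)
    assert m.total_delay_s == 12.0
    assert m.delay_by_doctor[1] == 12.0
    with pytest.raises(ValueError):
        m.accrue_delay(-1.0, doctor_id=1)


def test_utility_grows_by_requested_level_on_success_only():
    m = ShiftMetrics()
    m.update_utility(1, requested_level=5, success=True)
    m.update_utility(1, requested_level=4, success=False)
    m.update_utility(1, requested_level=1, success=True)
    assert m.utility_by_nurse[1] == 6.0
    assert m.successes_by_nurse[1] == 2
    assert m.failures_by_nurse[1] == 1


def test_per_entity_sums_equal_totals_on_real_runs():
    for scenario, policy in (("baseline", "fifo"), ("baseline", "ca"), ("training", "ca")):
        m, _ = run_shift(SimConfig(scenario=scenario, policy=policy, seed=6))
        assert sum(m.served_by_doctor.values()) == m.patients_served
        assert sum(m.damage_by_nurse.values()) == pytest.approx(m.time_damage_s)
        assert sum(m.damage_by_doctor.values()) == pytest.approx(m.time_damage_s)
        assert sum(m.delay_by_doctor.values()) == pytest.approx(m.total_delay_s)
        for nid in m.successes_by_nurse:
            assert m.tasks_by_nurse(nid) == m.successes_by_nurse[nid] + m.failures_by_nurse[nid]


def test_doctor_eval_accuracy_by_style():
    correct, _ = run_shift(SimConfig(scenario="baseline", policy="fifo", seed=1, shift_length_s=3000.0))
    for doc in correct.requests_by_doctor:
        assert correct.eval_accuracy(doc) == 1.0
    biased_cfg = SimConfig(
        scenario="baseline",
        policy="fifo",
        seed=1,
        shift_length_s=3000.0,
        doctors=[
            DoctorProfile(1, "overestimate", bias_magnitude=2, assigned_beds=tuple(range(1, 10)))
        ],
        level_probabilities={1: 0.5, 2: 0.3, 3: 0.2, 4: 0.0, 5: 0.0},
    )
    biased, _ = run_shift(biased_cfg)
    assert biased.eval_accuracy(1) == 0.0  # bias always displaces levels <= 3


def test_replay_from_csv_is_bit_exact(tmp_path, default_ca_config):
    metrics, log = run_shift(default_ca_config)
    path = log.write_csv(tmp_path / "events.csv")
    replayed = metrics_from_log(EventLog.read_csv(path).records)
    assert replayed == metrics


def test_replay_of_truncated_log_fails_loudly(tmp_path, default_ca_config):
    _, log = run_shift(default_ca_config)
    # cut inside a claim->completion pair: the completion now has no claim
    claims = [i for i, r in enumerate(log.records) if r.event == ev.CLAIM]
    broken = log.records[: claims[3]] + log.records[claims[3] + 1:]
    with pytest.raises(EventLogError):
        metrics_from_log(broken)


def test_empty_log_gives_all_zero_metrics():
    m = metrics_from_log([])
    assert m.patients_served == 0
    assert m.time_damage_s == 0.0
    assert m.total_delay_s == 0.0


def test_csv_export_totals_match_entity_sums(tmp_path, default_ca_config):
    import pandas as pd

    metrics, _ = run_shift(default_ca_config)
    meta = {"run_id": "r1", "scenario": "baseline", "policy": "ca", "seed": 7}
    paths = finalize_and_write(metrics, meta, tmp_path)
    runs = pd.read_csv(paths["runs"])
    doctors = pd.read_csv(paths["doctors"])
    nurses = pd.read_csv(paths["nurses"])
    assert runs.loc[0, "patients_served"] == doctors["patients_served"].sum()
    assert runs.loc[0, "time_damage_s"] == pytest.approx(nurses["time_damage_s"].sum())
    assert runs.loc[0, "time_damage_s"] == pytest.approx(doctors["time_damage_s"].sum())
    assert runs.loc[0, "total_delay_s"] == pytest.approx(doctors["total_delay_s"].sum())


def test_overestimating_doctor_never_reduces_failures():
    """A stricter requested threshold can only add failures on the same seed."""
    def with_style(style):
        return SimConfig(
            scenario="baseline", policy="fifo", seed=3, shift_length_s=6000.0,
            doctors=[DoctorProfile(1, style, bias_magnitude=2, assigned_beds=tuple(range(1, 10)))],
        )

    m_correct, _ = run_shift(with_style("correct"))
    m_over, _ = run_shift(with_style("overestimate"))
    assert sum(m_over.failures_by_nurse.values()) >= sum(m_correct.failures_by_nurse.values())


def test_event_log_rejects_time_reversal():
    log = EventLog()
    log.add(5.0, ev.PATIENT_SPAWN, actor=1, bed=1)
    with pytest.raises(EventLogError):
        log.add(4.0, ev.PATIENT_SPAWN, actor=2, bed=2)


def test_event_record_detail_round_trip(tmp_path):
    log = EventLog()
    log.add(1.5, ev.TASK_COMPLETE, actor=1, bed=2, request=3, level=4,
            detail={"doctor": 1, "patient": 9, "true_level": 2,
                    "requested_duration_s": 30.0, "actual_duration_s": 33.03000000000001,
                    "success": False})
    path = log.write_csv(tmp_path / "e.csv")
    back = EventLog.read_csv(path)
    assert back.records == log.records
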