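"""Agent competence models: doctor difficulty evaluation, nurse task durations, mentoring.

The simulated nursing task (IV-catheter insertion) carries an integer difficulty
level from 1 (easiest) to 5 (most difficult).  Each level has a *gold-standard*
execution duration: harder tasks are more urgent and therefore demand faster
execution, so the map is strictly decreasing in level.  A doctor estimates the
level after examining a patient, possibly with a systematic bias; a nurse's
execution time is the gold duration scaled by her speed factor and, optionally,
multiplicative lognormal noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.special import ndtri

LEVELS: tuple[int, ...] = (1, 2, 3, 4, 5)
MIN_LEVEL, MAX_LEVEL = 1, 5

#: Default level -> gold-standard duration (seconds): 70 - 10 * level.
#: Passes through the two anchor points level 3 -> 40 s and level 5 -> 20 s.
DEFAULT_GOLD_DURATIONS: dict[int, float] = {lvl: float(70 - 10 * lvl) for lvl in LEVELS}

DOCTOR_STYLES = ("correct", "overestimate", "underestimate")
NURSE_QUALITIES = ("high", "low")
NURSE_ROLES = ("regular", "replacement", "trainer")


def validate_level(level: int) -> int:
    """Return ``level`` as int, rejecting anything outside 1..5."""
    lvl = int(level)
    if lvl != level or not MIN_LEVEL <= lvl <= MAX_LEVEL:
        raise ValueError(f"performance level must be an integer in 1..5, got {level!r}")
    return lvl


class LevelDurationMap:
    """Strictly decreasing map level -> gold-standard duration in seconds."""

    def __init__(self, durations: dict[int, float] | None = None):
        durations = dict(durations) if durations is not None else dict(DEFAULT_GOLD_DURATIONS)
        if sorted(durations) != list(LEVELS):
            raise ValueError("duration map must cover exactly levels 1..5")
        values = [float(durations[lvl]) for lvl in LEVELS]
        if any(v <= 0 for v in values):
            raise ValueError("gold durations must be positive")
        if any(a <= b for a, b in zip(values, values[1:])):
            raise ValueError("gold durations must be strictly decreasing in level")
        self._durations = {lvl: float(durations[lvl]) for lvl in LEVELS}

    def duration(self, level: int) -> float:
        return self._durations[validate_level(level)]

    def as_dict(self) -> dict[int, float]:
        return dict(self._durations)

    def __eq__(self, other) -> bool:
        return isinstance(other, LevelDurationMap) and self._durations == other._durations

    def __repr__(self) -> str:
        return f"LevelDurationMap({self._durations})"


@dataclass(frozen=True)
class DoctorProfile:
    """A doctor's evaluation style and bed assignment.

    ``style`` is one of ``correct`` / ``overestimate`` / ``underestimate``;
    biased styles shift the estimated level by ``bias_magnitude`` (clamped to 1..5).
    """

    doctor_id: int
    style: str = "correct"
    bias_magnitude: int = 2
    exam_duration_s: float = 10.0
    assigned_beds: tuple[int, ...] = ()

    def __post_init__(self):
        if self.style not in DOCTOR_STYLES:
            raise ValueError(f"unknown evaluation style {self.style!r}")
        if self.style != "correct" and self.bias_magnitude < 1:
            raise ValueError("bias_magnitude must be >= 1 for a biased style")
        if self.exam_duration_s < 0:
            raise ValueError("exam_duration_s must be non-negative")


@dataclass
class NurseProfile:
    """A nurse's quality attribute and execution-time parameters.

    ``speed_factor`` multiplies the gold-standard duration (high quality < 1 <=
    low quality); ``noise_sd`` is the sigma of multiplicative lognormal noise.
    ``speed_factor`` is mutable: mentoring in the Training scenario lowers it.
    """

    nurse_id: int
    quality: str = "high"
    speed_factor: float = 0.9
    noise_sd: float = 0.10
    role: str = "regular"

    def __post_init__(self):
        if self.quality not in NURSE_QUALITIES:
            raise ValueError(f"unknown nurse quality {self.quality!r}")
        if self.role not in NURSE_ROLES:
            raise ValueError(f"unknown nurse role {self.role!r}")
        if self.speed_factor <= 0:
            raise ValueError("speed_factor must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class TrainingState:
    """Progress of a mentored low performer toward the high-quality speed factor."""

    observed_count: int = 0
    active: bool = False
    completion_threshold: float = 0.9
    decrement: float = 0.002
    floor: float = 0.9


def evaluate_performance_level(true_level: int, profile: DoctorProfile) -> int:
    """Map a task's true difficulty to the doctor's estimate.

    Deterministic given the profile: the ``correct`` style is the identity,
    ``overestimate`` adds the bias magnitude (clamped at 5), ``underestimate``
    subtracts it (clamped at 1).
    """
    lvl = validate_level(true_level)
    if profile.style == "correct":
        return lvl
    if profile.style == "overestimate":
        return min(MAX_LEVEL, lvl + profile.bias_magnitude)
    return max(MIN_LEVEL, lvl - profile.bias_magnitude)


def gold_duration(level: int, duration_map: LevelDurationMap | None = None) -> float:
    """Gold-standard execution time (seconds) for a difficulty level."""
    dmap = duration_map if duration_map is not None else _DEFAULT_MAP
    return dmap.duration(level)


_DEFAULT_MAP = LevelDurationMap()


def noise_multiplier(noise_sd: float, rng_draw: float | None) -> float:
    """Lognormal noise factor exp(sigma * Phi^-1(u)) from a unit-interval draw.

    ``rng_draw=None`` disables noise (factor 1.0), the deterministic test mode.
    The factor has median 1: draws above/below u=0.5 slow down/speed up the task.
    """
    if rng_draw is None or noise_sd == 0.0:
        return 1.0
    if not 0.0 < rng_draw < 1.0:
        raise ValueError("rng_draw must lie strictly inside the unit interval")
    return math.exp(noise_sd * float(ndtri(rng_draw)))


def get_task_duration(
    nurse: NurseProfile,
    training: TrainingState | None,
    true_level: int,
    rng_draw: float | None = None,
    duration_map: LevelDurationMap | None = None,
) -> float:
    """Actual execution time for one task: gold duration x speed factor x noise.

    The execution time is driven by the task's *true* difficulty (what the
    patient actually needs), not the doctor's estimate.  Trainer nurses observe
    but never execute, so asking one for a duration is a contract violation.
    """
    if nurse.role == "trainer":
        raise ValueError("trainer nurses do not execute tasks")
    base = gold_duration(true_level, duration_map)
    duration = base * nurse.speed_factor * noise_multiplier(nurse.noise_sd, rng_draw)
    if duration <= 0:
        raise ValueError("task duration must be strictly positive")
    return duration


def apply_training_increment(
    training: TrainingState, nurse: NurseProfile
) -> tuple[TrainingState, NurseProfile]:
    """Register one mentored task completion and improve the trainee.

    The speed factor drops by the configured decrement, floored at the
    high-quality default; training deactivates once the factor reaches the
    completion threshold.  Calling this while inactive is a no-op (flagged by
    the caller's event log).
    """
    if not training.active:
        return training, nurse
    training.observed_count += 1
    nurse.speed_factor = max(training.floor, nurse.speed_factor - training.decrement)
    if nurse.speed_factor <= training.completion_threshold:
        training.active = False
    return training, nurse


def training_steps_to_floor(initial: float, floor: float, decrement: float) -> int:
    """Closed-form number of mentored completions needed to reach the floor."""
    if initial <= floor:
        return 0
    # epsilon guards the ceiling against float dust in (initial - floor)
    return math.ceil((initial - floor) / decrement - 1e-9)
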