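"""Run configuration: agents, scenario, policy, durations, trust parameters, seed.

The default configuration reproduces the case-study emergency room: three
doctors who all estimate task difficulty correctly (beds 1-3, 4-6, 7-9), one
high-performing and one low-performing nurse, nine beds filled in the order
1,4,7,2,5,8,3,6,9, a 10 s examination delay, and an 8-hour shift under
saturated patient demand.

Configs are plain dataclasses; they round-trip through dicts and can be read
from TOML or YAML files and dumped back to TOML.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .behavior import (
    DEFAULT_GOLD_DURATIONS,
    LEVELS,
    DoctorProfile,
    LevelDurationMap,
    NurseProfile,
)

SCENARIOS = ("baseline", "replacement", "training")
POLICIES = ("ca", "fifo")

BED_FILL_ORDER = (1, 4, 7, 2, 5, 8, 3, 6, 9)

HIGH_SPEED_FACTOR = 0.9
LOW_SPEED_FACTOR = 1.5
HIGH_NOISE_SD = 0.10
LOW_NOISE_SD = 0.25


class ConfigError(ValueError):
    """Invalid run configuration (raised before any event is simulated)."""


@dataclass
class TrustConfig:
    """Parameters of the CA trust policy."""

    initial_weight: float = 0.8
    learning_rate: float = 0.1
    threshold: float = 0.5
    min_attempts: int = 3
    baseline_cap: int = 2  # max level an unreliable nurse may keep (Baseline/Replacement)


@dataclass
class TrainingConfig:
    """Parameters of the mentoring (Training) scenario."""

    decrement: float = 0.002  # speed-factor gain per mentored completion
    floor: float = HIGH_SPEED_FACTOR
    completion_threshold: float = HIGH_SPEED_FACTOR


@dataclass
class SimConfig:
    """Full parameterization of one simulated shift."""

    scenario: str = "baseline"
    policy: str = "ca"
    seed: int = 0
    run_id: Optional[str] = None
    shift_length_s: float = 28_800.0
    travel_time_s: float = 5.0
    exam_duration_s: float = 10.0
    n_beds: int = 9
    bed_fill_order: tuple[int, ...] = BED_FILL_ORDER
    #: ``None`` means "use the case-study default roster"; an explicit empty
    #: list is honored (degenerate configurations are legal and testable)
    doctors: Optional[list[DoctorProfile]] = None
    nurses: Optional[list[NurseProfile]] = None
    level_duration_s: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_GOLD_DURATIONS)
    )
    #: probability of each true difficulty level (uniform by default)
    level_probabilities: dict[int, float] = field(
        default_factory=lambda: {lvl: 0.2 for lvl in LEVELS}
    )
    noise_enabled: bool = True
    trust: TrustConfig = field(default_factory=TrustConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)

    def __post_init__(self):
        if self.doctors is None:
            self.doctors = default_doctors(exam_duration_s=self.exam_duration_s)
        if self.nurses is None:
            self.nurses = default_nurses()

    @property
    def duration_map(self) -> LevelDurationMap:
        return LevelDurationMap(self.level_duration_s)

    def combo(self) -> str:
        return f"{self.scenario}-{self.policy}"


def default_doctors(
    n: int = 3, style: str = "correct", exam_duration_s: float = 10.0, n_beds: int = 9
) -> list[DoctorProfile]:
    """Doctors with contiguous, disjoint bed blocks (doctor 1 -> beds 1-3, ...)."""
    per = n_beds // n
    return [
        DoctorProfile(
            doctor_id=i + 1,
            style=style,
            exam_duration_s=exam_duration_s,
            assigned_beds=tuple(range(i * per + 1, (i + 1) * per + 1)),
        )
        for i in range(n)
    ]


def default_nurses() -> list[NurseProfile]:
    """One high- and one low-performing nurse, the case-study roster."""
    return [
        NurseProfile(1, "high", HIGH_SPEED_FACTOR, HIGH_NOISE_SD),
        NurseProfile(2, "low", LOW_SPEED_FACTOR, LOW_NOISE_SD),
    ]


def high_performer_profile(nurse_id: int, role: str = "replacement") -> NurseProfile:
    return NurseProfile(nurse_id, "high", HIGH_SPEED_FACTOR, HIGH_NOISE_SD, role=role)


def validate_config(config: SimConfig) -> SimConfig:
    """Check the scenario/policy combination, bed coverage, and parameter ranges."""
    if config.scenario not in SCENARIOS:
        raise ConfigError(f"unknown scenario {config.scenario!r}")
    if config.policy not in POLICIES:
        raise ConfigError(f"unknown policy {config.policy!r}")
    if config.policy == "fifo" and config.scenario != "baseline":
        raise ConfigError(
            "the FIFO policy is only meaningful in the Baseline scenario: it has no "
            "self-assessment, so Replacement/Training hooks can never fire"
        )
    if config.shift_length_s <= 0:
        raise ConfigError("shift_length_s must be positive")
    if config.travel_time_s < 0:
        raise ConfigError("travel_time_s must be non-negative")
    beds = set(range(1, config.n_beds + 1))
    if sorted(config.bed_fill_order) != sorted(beds):
        raise ConfigError("bed_fill_order must be a permutation of the bed ids")
    covered: set[int] = set()
    for doc in config.doctors:
        owned = set(doc.assigned_beds)
        if owned & covered:
            raise ConfigError(f"doctor {doc.doctor_id} shares beds with another doctor")
        covered |= owned
    if covered != beds:
        raise ConfigError("doctor bed assignments must cover all beds exactly once")
    ids = [n.nurse_id for n in config.nurses]
    if len(ids) != len(set(ids)):
        raise ConfigError("nurse ids must be unique")
    probs = config.level_probabilities
    if sorted(probs) != list(LEVELS) or abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ConfigError("level_probabilities must cover levels 1..5 and sum to 1")
    config.duration_map  # raises on a non-decreasing table
    return config


# ---------------------------------------------------------------------------
# (de)serialization


def config_to_dict(config: SimConfig) -> dict:
    out = asdict(config)
    out["bed_fill_order"] = list(config.bed_fill_order)
    for doc in out["doctors"]:
        doc["assigned_beds"] = list(doc["assigned_beds"])
    out["level_duration_s"] = {str(k): v for k, v in config.level_duration_s.items()}
    out["level_probabilities"] = {str(k): v for k, v in config.level_probabilities.items()}
    return out


def config_from_dict(data: dict) -> SimConfig:
    data = dict(data)
    doctors = [
        DoctorProfile(
            doctor_id=d["doctor_id"],
            style=d.get("style", "correct"),
            bias_magnitude=d.get("bias_magnitude", 2),
            exam_duration_s=d.get("exam_duration_s", 10.0),
            assigned_beds=tuple(d.get("assigned_beds", ())),
        )
        for d in data.pop("doctors", [])
    ] or None
    nurses = [
        NurseProfile(
            nurse_id=n["nurse_id"],
            quality=n.get("quality", "high"),
            speed_factor=n.get("speed_factor", HIGH_SPEED_FACTOR),
            noise_sd=n.get("noise_sd", HIGH_NOISE_SD),
            role=n.get("role", "regular"),
        )
        for n in data.pop("nurses", [])
    ] or None
    trust = TrustConfig(**data.pop("trust", {}))
    training = TrainingConfig(**data.pop("training", {}))
    if "bed_fill_order" in data:
        data["bed_fill_order"] = tuple(data["bed_fill_order"])
    if "level_duration_s" in data:
        data["level_duration_s"] = {int(k): float(v) for k, v in data["level_duration_s"].items()}
    if "level_probabilities" in data:
        data["level_probabilities"] = {
            int(k): float(v) for k, v in data["level_probabilities"].items()
        }
    known = SimConfig.__dataclass_fields__
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    return SimConfig(doctors=doctors, nurses=nurses, trust=trust, training=training, **data)


def load_config(path: str | Path) -> SimConfig:
    """Read a SimConfig from a TOML (default) or YAML file."""
    path = Path(path)
    text = path.read_bytes()
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(text)
    else:
        data = tomllib.loads(text.decode())
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return validate_config(config_from_dict(data))


def _toml_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return json.dumps(value)
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise TypeError(f"cannot render {value!r} as TOML")


def dump_config_toml(config: SimConfig) -> str:
    """Render a SimConfig as TOML text (readable back by :func:`load_config`)."""
    data = config_to_dict(config)
    doctors = data.pop("doctors")
    nurses = data.pop("nurses")
    trust = data.pop("trust")
    training = data.pop("training")
    tables = {"level_duration_s": data.pop("level_duration_s"),
              "level_probabilities": data.pop("level_probabilities"),
              "trust": trust, "training": training}
    lines = []
    for key, value in data.items():
        if value is None:
            continue
        lines.append(f"{key} = {_toml_value(value)}")
    for name, table in tables.items():
        lines.append(f"\n[{name}]")
        lines.extend(f'"{k}" = {_toml_value(v)}' if name.startswith("level") else
                     f"{k} = {_toml_value(v)}" for k, v in table.items())
    for name, rows in (("doctors", doctors), ("nurses", nurses)):
        for row in rows:
            lines.append(f"\n[[{name}]]")
            lines.extend(f"{k} = {_toml_value(v)}" for k, v in row.items())
    return "\n".join(lines) + "\n"


def config_hash(config: SimConfig) -> str:
    """SHA-256 of the canonical JSON form (stable under key reordering)."""
    canonical = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
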