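import pytest

from edtrust.behavior import DoctorProfile, NurseProfile
from edtrust.config import SimConfig


@pytest.fixture
def tiny_config():
    """1 doctor / 3 beds / 2 nurses, noise off: small enough to hand-check."""
    return SimConfig(
        scenario="baseline",
        policy="fifo",
        seed=0,
        shift_length_s=600.0,
        n_beds=3,
        bed_fill_order=(1, 2, 3),
        doctors=[DoctorProfile(1, "correct", assigned_beds=(1, 2, 3))],
        nurses=[
            NurseProfile(1, "high", 0.9, 0.10),
            NurseProfile(2, "low", 1.5, 0.25),
        ],
        noise_enabled=False,
    )


@pytest.fixture
def single_server_config():
    """1 doctor / 1 bed / 1 high nurse, constant level 3, noise off.

    The shift degenerates to a fixed service cycle: 10 s exam + 5 s travel +
    0.9 x 40 s execution = 51 s per patient (the 5 s return overlaps the exam).
    """
    return SimConfig(
        scenario="baseline",
        policy="fifo",
        seed=0,
        shift_length_s=600.0,
        n_beds=1,
        bed_fill_order=(1,),
        doctors=[DoctorProfile(1, "correct", assigned_beds=(1,))],
        nurses=[NurseProfile(1, "high", 0.9, 0.10)],
        level_probabilities={1: 0.0, 2: 0.0, 3: 1.0, 4: 0.0, 5: 0.0},
        noise_enabled=False,
    )


@pytest.fixture
def default_ca_config():
    return SimConfig(scenario="baseline", policy="ca", seed=7)
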