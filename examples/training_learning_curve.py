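"""Trace the mentored nurse's learning curve in the Training scenario.

Once the low performer self-assesses as unreliable, a trainer nurse joins her;
every mentored completion nudges her speed factor toward the high-quality
value and the trainer leaves when she reaches it.  The printout shows when
mentoring started and ended and her mean executed task duration per shift
third — a falling sequence is the within-shift skill gain.
"""

from edtrust import SimConfig, nurse_duration_thirds, run_shift
from edtrust import eventlog as ev

config = SimConfig(scenario="training", policy="ca", seed=0)
metrics, log = run_shift(config)

spawn = log.of_kind(ev.TRAINER_SPAWN)[0]
exits = log.of_kind(ev.TRAINER_EXIT)
progress = log.of_kind(ev.TRAINING_PROGRESS)
print(f"trainer joined at t = {spawn.time_s:8.1f} s (trainee: nurse {spawn.detail['trainee']})")
if exits:
    print(f"trainer left at   t = {exits[0].time_s:8.1f} s "
          f"after {progress[-1].detail['observed_count']} mentored tasks")
print(f"speed factor: {progress[0].detail['speed_factor']:.3f} -> "
      f"{progress[-1].detail['speed_factor']:.3f}")

thirds = nurse_duration_thirds(log, nurse_id=2, shift_length_s=config.shift_length_s)
print("mean executed duration per shift third: "
      + "  ".join(f"{t:.1f} s" for t in thirds))
# Each third should be faster than the last while mentoring is in progress.
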