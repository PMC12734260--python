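"""Round-trip a run through its event log: metrics are a pure function of it.

Writes the CSV event log of one shift, reads it back, recomputes every metric
from the parsed records, and checks bit-exact agreement with the live run —
the property behind the ``edtrust replay`` command.
"""

import tempfile
from pathlib import Path

from edtrust import EventLog, SimConfig, metrics_from_log, run_shift

config = SimConfig(scenario="replacement", policy="ca", seed=5)
metrics, log = run_shift(config)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "events.csv"
    log.write_csv(path)
    replayed = metrics_from_log(EventLog.read_csv(path).records)

print(f"records written : {len(log)}")
print(f"served (live)   : {metrics.patients_served}")
print(f"served (replay) : {replayed.patients_served}")
print(f"damage (live)   : {metrics.time_damage_s!r}")
print(f"damage (replay) : {replayed.time_damage_s!r}")
print(f"bit-exact       : {replayed == metrics}")
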