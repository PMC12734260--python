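"""Simulate one 8-hour emergency-room shift under the CA trust policy.

Three doctors (all estimating task difficulty correctly) broadcast one
IV-catheter request per examined patient; a high- and a low-performing nurse
claim them trust-aware.  The printed totals are the shift's headline metrics:
patients fully served, cumulative excess execution time ("time damage", a
patient-harm proxy), and the total time patients waited with an issued but
unclaimed request.
"""

from edtrust import SimConfig, run_shift

config = SimConfig(scenario="baseline", policy="ca", seed=42)
metrics, log = run_shift(config)

print(f"scenario={config.scenario} policy={config.policy} seed={config.seed}")
print(f"patients served : {metrics.patients_served}")
print(f"time damage     : {metrics.time_damage_s:9.1f} s")
print(f"total delay     : {metrics.total_delay_s:9.1f} s")
for nid in sorted(metrics.successes_by_nurse):
    print(
        f"nurse {nid}: {metrics.successes_by_nurse[nid]:4d} ok "
        f"{metrics.failures_by_nurse[nid]:4d} failed "
        f"utility {metrics.utility_by_nurse[nid]:6.0f}"
    )
print(f"event log: {len(log)} records")
# The low performer fails until self-assessment sidelines her: few failures,
# little damage, but fewer patients served than a FIFO shift would manage.
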