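"""Generate a synthetic volunteer-network alert log and write it as CSVs.

The default configuration emulates a year of an opioid-overdose response
community: 112 volunteers, 188 events, 5 candidates alerted per event,
persistent per-volunteer response propensities.
"""
from vfrdispatch import generate_alert_log, validate_log, write_alert_log

log = generate_alert_log(seed=1)
print(f"volunteers: {len(log.volunteers)}")
print(f"events:     {len(log.events)} "
      f"({sum(e.false_alarm for e in log.events.values())} false alarms)")
print(f"alerts:     {log.n_alerts}")

answer_rate = sum(a.answered for a in log.alerts) / log.n_alerts
print(f"answer rate: {answer_rate:.3f}  "
      "(share of alerts with any reaction other than silence)")

violations = validate_log(log)
print(f"invariant violations: {len(violations)}")

paths = write_alert_log(log, "scratch/example_log")
print("wrote:", ", ".join(str(p) for p in paths.values()))
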