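"""Build per-alert behavioral history features and the frequent-responder
indicator.

Each alert is described by seven cumulative counters over the responder's
strictly earlier alerts (alert counts, false-alarm exposure, same-signaler
contacts, past responses), plus a dynamic frequent-responder flag whose
response-rate threshold relaxes as the volunteer accumulates alerts.
"""
from vfrdispatch import generate_alert_log, frequent_responder
from vfrdispatch.features import build_instances, history_table

log = generate_alert_log(seed=1)
hist = history_table(log)
print("history counters for the last alert of the log:")
print(hist.iloc[-1].to_string())

a, r = int(hist.iloc[-1]["prev_alerts"]), int(hist.iloc[-1]["prev_responses"])
print(f"\nfrequent responder({a} alerts, {r} responses) -> {frequent_responder(a, r)}")
print("rule: <6 alerts no; 6-10 need >=50%; 11-20 >=40%; 21-30 >=30%; >=31 >=25%")

for model_id in (1, 2, 3, 4):
    df = build_instances(log, model_id)
    feats = [c for c in df.columns
             if c not in ("alert_id", "model_id", "alert_time", "label")]
    print(f"model {model_id}: {len(df)} instances, features: {feats}")
print("(instances exclude alerts of false-alarm events; "
      "history still counts them)")
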