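"""Per-alert behavioral history features, the frequent-responder rule,
labels, and the four model-specific instance tables.

History is *causal*: every counter aggregates only alerts to the same
responder that are strictly earlier in the global ``(alert_time, alert_id)``
order, so no feature leaks information from the future.  History spans
alerts of false-alarm events (a volunteer's reaction to a false alarm is
informative), even though alerts of false-alarm events are excluded as
classification instances.

The four model configurations differ only in their feature sets:

==== ==========================================================
1    event/alert context: weekday_weekend, day_night, distance_m
2    model 1 + the seven raw history counters
3    model 1 + demographics + condition-specific experience
4    model 3 + the dynamic frequent_responder indicator
==== ==========================================================
"""
from __future__ import annotations

from dataclasses import dataclass, astuple
from typing import Iterable

import numpy as np
import pandas as pd

from .data_model import Alert, AlertLog

__all__ = [
    "HISTORY_COLUMNS", "MODEL_FEATURES", "HistoryFeatures",
    "history_features", "history_table", "frequent_responder",
    "label_alert", "build_instances", "write_instances",
]

HISTORY_COLUMNS = (
    "prev_alerts", "prev_false_alerts", "prev_alerts_same_signaler",
    "prev_false_alerts_same_signaler", "prev_responses",
    "prev_responses_false", "prev_responses_false_same_signaler",
)

_CONTEXT = ("weekday_weekend", "day_night", "distance_m")
_DEMOGRAPHICS = ("age", "gender", "homeless", "employment",
                 "naloxone_carriage", "witnessed_band", "administered_band")

#: Exact feature set per model configuration.
MODEL_FEATURES: dict[int, tuple[str, ...]] = {
    1: _CONTEXT,
    2: _CONTEXT + HISTORY_COLUMNS,
    3: _CONTEXT + _DEMOGRAPHICS,
    4: _CONTEXT + _DEMOGRAPHICS + ("frequent_responder",),
}


@dataclass(frozen=True)
class HistoryFeatures:
    """The seven cumulative counters for one alert's responder."""

    prev_alerts: int
    prev_false_alerts: int
    prev_alerts_same_signaler: int
    prev_false_alerts_same_signaler: int
    prev_responses: int
    prev_responses_false: int
    prev_responses_false_same_signaler: int

    def as_tuple(self) -> tuple[int, ...]:
        return astuple(self)


class _HistoryAccumulator:
    """Single forward pass over an ordered alert sequence.

    Per volunteer: total alerts / false-alert / response / false-response
    counts; per (volunteer, signaler): alert, false-alert and
    false-response counts.
    """

    def __init__(self, log: AlertLog):
        self._log = log
        self._totals: dict[str, np.ndarray] = {}
        self._by_signaler: dict[tuple[str, str], np.ndarray] = {}

    def features_for(self, alert: Alert) -> HistoryFeatures:
        signaler = self._log.event_of(alert).signaler_id
        tot = self._totals.get(alert.responder_id)
        if tot is None:
            tot = np.zeros(4, dtype=int)
        sig = self._by_signaler.get((alert.responder_id, signaler))
        if sig is None:
            sig = np.zeros(3, dtype=int)
        return HistoryFeatures(
            prev_alerts=int(tot[0]), prev_false_alerts=int(tot[1]),
            prev_alerts_same_signaler=int(sig[0]),
            prev_false_alerts_same_signaler=int(sig[1]),
            prev_responses=int(tot[2]), prev_responses_false=int(tot[3]),
            prev_responses_false_same_signaler=int(sig[2]))

    def push(self, alert: Alert) -> None:
        event = self._log.event_of(alert)
        responded = alert.answered
        tot = self._totals.setdefault(alert.responder_id, np.zeros(4, dtype=int))
        tot += (1, event.false_alarm, responded, event.false_alarm and responded)
        sig = self._by_signaler.setdefault(
            (alert.responder_id, event.signaler_id), np.zeros(3, dtype=int))
        sig += (1, event.false_alarm, event.false_alarm and responded)


def history_features(log: AlertLog, alert: Alert) -> HistoryFeatures:
    """Compute the seven counters for one alert by scanning its log prefix.

    A "response" is any final status other than ``no_answer``; "same
    signaler" compares each historical alert's event signaler with the
    current event's signaler.
    """
    if alert.alert_id not in {a.alert_id for a in log.alerts}:
        raise KeyError(f"alert {alert.alert_id!r} not in log")
    acc = _HistoryAccumulator(log)
    key = alert.sort_key()
    for past in log.alerts:
        if past.sort_key() >= key:
            break
        if past.responder_id == alert.responder_id:
            acc.push(past)
    return acc.features_for(alert)


def history_table(log: AlertLog) -> pd.DataFrame:
    """Seven history counters for every alert, indexed by alert_id (one pass)."""
    acc = _HistoryAccumulator(log)
    rows = []
    for alert in log.alerts:
        rows.append((alert.alert_id, *acc.features_for(alert).as_tuple()))
        acc.push(alert)
    return pd.DataFrame(rows, columns=("alert_id", *HISTORY_COLUMNS)).set_index("alert_id")


def frequent_responder(prev_alerts: int, prev_responses: int) -> bool:
    """The dynamic frequent-responder indicator.

    The alert-count-dependent response-rate thresholds are: fewer than 6
    alerts → no; 6-10 alerts → rate ≥ 50%; 11-20 → ≥ 40%; 21-30 → ≥ 30%;
    31 or more → ≥ 25%.
    """
    if prev_responses > prev_alerts:
        raise ValueError("prev_responses exceeds prev_alerts")
    if prev_alerts < 0 or prev_responses < 0:
        raise ValueError("counts must be non-negative")
    if prev_alerts < 6:
        return False
    rate = prev_responses / prev_alerts
    if prev_alerts <= 10:
        return rate >= 0.50
    if prev_alerts <= 20:
        return rate >= 0.40
    if prev_alerts <= 30:
        return rate >= 0.30
    return rate >= 0.25


def label_alert(log: AlertLog, alert: Alert) -> str:
    """Label an alert ``responded`` / ``ignored`` / ``excluded``.

    Alerts of false-alarm events are excluded from classification;
    ``no_answer`` on a true alarm is ``ignored``; every other final status
    (including canceled dispatch) counts as ``responded``.
    """
    if log.event_of(alert).false_alarm:
        return "excluded"
    return "responded" if alert.answered else "ignored"


def build_instances(log: AlertLog, model_id: int) -> pd.DataFrame:
    """Build the labeled instance table for one model configuration.

    Rows are chronological (the log's alert order); alerts of false-alarm
    events are dropped.  Columns: ``alert_id``, ``model_id``,
    ``alert_time`` (metadata, used by the chronological evaluation
    protocol), the model's features, and ``label``.  Missing distances stay
    missing (NaN) for the learner's fractional routing.
    """
    if model_id not in MODEL_FEATURES:
        raise ValueError(f"model_id must be one of {sorted(MODEL_FEATURES)}, got {model_id}")
    feats = MODEL_FEATURES[model_id]
    hist = history_table(log) if (model_id == 2 or model_id == 4) else None

    rows = []
    for alert in log.alerts:
        label = label_alert(log, alert)
        if label == "excluded":
            continue
        event = log.event_of(alert)
        row: dict[str, object] = {
            "alert_id": alert.alert_id, "model_id": model_id,
            "alert_time": alert.alert_time,
        }
        for name in feats:
            if name == "weekday_weekend":
                row[name] = event.weekday_weekend
            elif name == "day_night":
                row[name] = event.day_night
            elif name == "distance_m":
                row[name] = np.nan if alert.distance_m is None else float(alert.distance_m)
            elif name in HISTORY_COLUMNS:
                row[name] = int(hist.loc[alert.alert_id, name])
            elif name == "frequent_responder":
                h = hist.loc[alert.alert_id]
                row[name] = frequent_responder(int(h["prev_alerts"]),
                                               int(h["prev_responses"]))
            else:  # volunteer attribute
                row[name] = getattr(log.volunteer_of(alert), name)
        row["label"] = label
        rows.append(row)

    columns = ["alert_id", "model_id", "alert_time", *feats, "label"]
    df = pd.DataFrame(rows, columns=columns)
    if df.empty:
        return df
    # keep crisp dtypes for the learner's numeric/categorical inference
    for col in ("age", *HISTORY_COLUMNS):
        if col in df.columns:
            df[col] = df[col].astype(int)
    for col in ("homeless", "frequent_responder"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_instances(df: pd.DataFrame, path) -> None:
    """Write an instance table as CSV: alert_id, model_id, features, label."""
    df.drop(columns=["alert_time"], errors="ignore").to_csv(path, index=False)
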