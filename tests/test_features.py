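"""History counters, frequent-responder rule, labels, and instance tables."""
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from vfrdispatch.data_model import Alert, AlertLog, Event
from vfrdispatch.features import (HISTORY_COLUMNS, MODEL_FEATURES,
                                  build_instances, frequent_responder,
                                  history_features, history_table, label_alert,
                                  write_instances)
from vfrdispatch.synthetic import SyntheticConfig, generate_alert_log


def brute_force_history(log: AlertLog, alert: Alert) -> tuple[int, ...]:
    """Independent prefix recount, straight from the definitions."""
    signaler = log.event_of(alert).signaler_id
    key = alert.sort_key()
    prev = [a for a in log.alerts
            if a.responder_id == alert.responder_id and a.sort_key() < key]
    false = [a for a in prev if log.event_of(a).false_alarm]
    same = [a for a in prev if log.event_of(a).signaler_id == signaler]
    false_same = [a for a in same if log.event_of(a).false_alarm]
    resp = [a for a in prev if a.final_status != "no_answer"]
    resp_false = [a for a in false if a.final_status != "no_answer"]
    resp_false_same = [a for a in false_same if a.final_status != "no_answer"]
    return (len(prev), len(false), len(same), len(false_same),
            len(resp), len(resp_false), len(resp_false_same))


def rule_oracle(a: int, r: int) -> bool:
    """Independently coded frequent-responder thresholds."""
    if a < 6:
        return False
    for lo, hi, need in ((6, 10, 0.50), (11, 20, 0.40), (21, 30, 0.30)):
        if lo <= a <= hi:
            return r / a >= need
    return r / a >= 0.25


class TestHistoryFeatures:
    def test_first_alert_all_zero(self, tiny_log):
        h = history_features(tiny_log, tiny_log.alerts[0])
        assert h.as_tuple() == (0, 0, 0, 0, 0, 0, 0)

    def test_worked_example(self, tiny_log):
        """V answered a false alarm from S, ignored a true alarm from S, and
        is now alerted by S again: counters (2,1,2,1,1,1,1)."""
        h = history_features(tiny_log, tiny_log.alerts[2])
        assert h.as_tuple() == (2, 1, 2, 1, 1, 1, 1)

    def test_alert_not_in_log_rejected(self, tiny_log):
        stranger = Alert("A99", "E1", "V", 5_000, None, "no_answer")
        with pytest.raises(KeyError):
            history_features(tiny_log, stranger)

    def test_history_table_equals_bruteforce_on_synthetic_log(self, default_log):
        table = history_table(default_log)
        for alert in default_log.alerts:
            expected = brute_force_history(default_log, alert)
            assert tuple(table.loc[alert.alert_id]) == expected

    def test_counters_monotone_per_volunteer(self, default_log):
        """Global counters never decrease along a volunteer's sequence; the
        same-signaler counters never decrease along a (volunteer, signaler)
        subsequence (they are relative to the current event's signaler)."""
        table = history_table(default_log)
        global_cols = ["prev_alerts", "prev_false_alerts", "prev_responses",
                       "prev_responses_false"]
        signaler_cols = ["prev_alerts_same_signaler",
                         "prev_false_alerts_same_signaler",
                         "prev_responses_false_same_signaler"]
        by_vol: dict[str, list] = {}
        by_pair: dict[tuple, list] = {}
        for a in default_log.alerts:
            by_vol.setdefault(a.responder_id, []).append(a.alert_id)
            sig = default_log.event_of(a).signaler_id
            by_pair.setdefault((a.responder_id, sig), []).append(a.alert_id)
        for ids in by_vol.values():
            assert (table.loc[ids, global_cols].diff().dropna() >= 0).all().all()
        for ids in by_pair.values():
            assert (table.loc[ids, signaler_cols].diff().dropna() >= 0).all().all()

    def test_causality_future_alerts_do_not_change_history(self, tiny_log):
        target = tiny_log.alerts[2]
        before = history_features(tiny_log, target)
        tiny_log.events["E9"] = Event("E9", 9_000, False, "S")
        tiny_log.alerts.append(Alert("A9", "E9", "V", 9_000, None, "done"))
        tiny_log.sort_alerts()
        assert history_features(tiny_log, target) == before

    def test_invariant_inequalities_hold(self, default_log):
        t = history_table(default_log)
        assert (t.prev_false_alerts <= t.prev_alerts).all()
        assert (t.prev_alerts_same_signaler <= t.prev_alerts).all()
        assert (t.prev_responses <= t.prev_alerts).all()
        assert (t.prev_responses_false
                <= np.minimum(t.prev_responses, t.prev_false_alerts)).all()
        assert (t.prev_responses_false_same_signaler
                <= np.minimum(t.prev_responses_false,
                              t.prev_false_alerts_same_signaler)).all()


class TestFrequentResponder:
    @pytest.mark.parametrize("a,r,expected", [
        (5, 5, False),      # below the 6-alert floor, whatever the rate
        (6, 3, True),       # 6-10 alerts need >= 50%
        (10, 4, False),
        (11, 5, True),      # 11-20 alerts need >= 40%
        (20, 7, False),
        (21, 7, True),      # 21-30 alerts need >= 30%
        (30, 8, False),     # 8/30 < 0.30
        (31, 8, True),      # >= 31 alerts need >= 25%; 8/31 >= 0.25
        (0, 0, False),
    ])
    def test_boundary_cases(self, a, r, expected):
        assert frequent_responder(a, r) is expected

    def test_exhaustive_agreement_with_rule_oracle(self):
        for a in range(61):
            for r in range(a + 1):
                assert frequent_responder(a, r) == rule_oracle(a, r), (a, r)

    def test_more_responses_than_alerts_rejected(self):
        with pytest.raises(ValueError):
            frequent_responder(3, 4)


class TestLabels:
    def test_no_answer_on_true_alarm_is_ignored(self, tiny_log):
        assert label_alert(tiny_log, tiny_log.alerts[1]) == "ignored"

    def test_no_go_on_true_alarm_is_responded(self, tiny_log):
        tiny_log.alerts.append(Alert("A5", "E2", "W", 2_100, None, "no_go"))
        tiny_log.sort_alerts()
        a5 = next(a for a in tiny_log.alerts if a.alert_id == "A5")
        assert label_alert(tiny_log, a5) == "responded"

    def test_canceled_dispatch_counts_as_responded(self, tiny_log):
        tiny_log.alerts.append(Alert("A6", "E2", "W", 2_100, None, "canceled_dispatch"))
        a6 = next(a for a in tiny_log.alerts if a.alert_id == "A6")
        assert label_alert(tiny_log, a6) == "responded"

    def test_false_alarm_event_excluded(self, tiny_log):
        assert label_alert(tiny_log, tiny_log.alerts[0]) == "excluded"


class TestInstanceTables:
    @pytest.mark.parametrize("model_id", [1, 2, 3, 4])
    def test_feature_sets_match_model_definition(self, default_log, model_id):
        df = build_instances(default_log, model_id)
        features = [c for c in df.columns
                    if c not in ("alert_id", "model_id", "alert_time", "label")]
        assert tuple(features) == MODEL_FEATURES[model_id]

    def test_model1_feature_names_exact(self, default_log):
        assert MODEL_FEATURES[1] == ("weekday_weekend", "day_night", "distance_m")

    def test_model4_has_indicator_not_raw_counters(self, default_log):
        df = build_instances(default_log, 4)
        assert "frequent_responder" in df.columns
        assert not set(HISTORY_COLUMNS) & set(df.columns)

    def test_all_false_alarm_log_gives_empty_table(self):
        cfg = replace(SyntheticConfig(), p_false_alarm=1.0, n_events=20, seed=1)
        log = generate_alert_log(cfg)
        assert build_instances(log, 1).empty

    def test_rows_chronological_and_exclude_false_alarms(self, default_log):
        df = build_instances(default_log, 2)
        assert (df["alert_time"].diff().dropna() >= 0).all()
        false_events = {e.event_id for e in default_log.events.values() if e.false_alarm}
        kept = {a.alert_id for a in default_log.alerts if a.event_id not in false_events}
        assert set(df["alert_id"]) == kept

    def test_indicator_recomputed_dynamically(self, default_log):
        """The model-4 indicator matches the rule applied to each alert's own
        history, so it can change within one volunteer's sequence."""
        df = build_instances(default_log, 4).set_index("alert_id")
        hist = history_table(default_log)
        for aid, row in df.iterrows():
            h = hist.loc[aid]
            assert row["frequent_responder"] == frequent_responder(
                int(h["prev_alerts"]), int(h["prev_responses"]))

    def test_invalid_model_id_rejected(self, default_log):
        with pytest.raises(ValueError):
            build_instances(default_log, 5)

    def test_csv_writer_drops_metadata_time(self, default_log, tmp_path):
        df = build_instances(default_log, 1)
        path = tmp_path / "instances.csv"
        write_instances(df, path)
        back = pd.read_csv(path)
        assert "alert_time" not in back.columns
        assert list(back.columns)[0] == "alert_id" and list(back.columns)[-1] == "label"
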