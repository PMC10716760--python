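"""Shared fixtures: a hand-built miniature log and session-scoped synthetic logs."""
from dataclasses import replace

import pytest

from vfrdispatch.data_model import Alert, AlertLog, Event, Volunteer
from vfrdispatch.synthetic import SyntheticConfig, generate_alert_log


def make_volunteer(vid, **kwargs):
    defaults = dict(age=40, gender="female", homeless=False,
                    employment="unemployed", naloxone_carriage="often",
                    witnessed_band="<=20", administered_band="<=20")
    defaults.update(kwargs)
    return Volunteer(volunteer_id=vid, **defaults)


@pytest.fixture
def tiny_log():
    """Three events by signaler S; volunteer V answered a false alarm, then
    ignored a true alarm, and is now alerted a third time."""
    volunteers = {vid: make_volunteer(vid) for vid in ("S", "V", "W")}
    events = {
        "E1": Event("E1", 1_000, True, "S"),
        "E2": Event("E2", 2_000, False, "S"),
        "E3": Event("E3", 3_000, False, "S"),
    }
    alerts = [
        Alert("A1", "E1", "V", 1_000, 500.0, "no_go"),
        Alert("A2", "E2", "V", 2_000, 800.0, "no_answer"),
        Alert("A3", "E3", "V", 3_000, None, "done"),
        Alert("A4", "E3", "W", 3_001, 1200.0, "no_answer"),
    ]
    return AlertLog(volunteers=volunteers, events=events, alerts=alerts)


@pytest.fixture(scope="session")
def default_log():
    """A study-sized synthetic log (112 volunteers, 188 events, 940 alerts)."""
    return generate_alert_log(seed=7)


@pytest.fixture(scope="session")
def large_log():
    """~5,000-alert log for heterogeneity / oracle checks."""
    cfg = replace(SyntheticConfig(), n_events=1_000, seed=42)
    return generate_alert_log(cfg)
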