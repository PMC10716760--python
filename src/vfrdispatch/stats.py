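"""Descriptive and inferential statistics for alert logs.

Reproduces, for any :class:`~vfrdispatch.data_model.AlertLog`, the study's
responded-vs-ignored comparison table (chi-square tests of independence
for categorical variables, pooled-variance two-tailed t tests for numeric
ones, no continuity correction, no multiple-testing adjustment — these
choices reproduce the published p-values from the published contingency
tables) and the final-status share table over true-alarm alerts.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import AlertLog, FINAL_STATUSES
from .features import HISTORY_COLUMNS, history_table, label_alert

__all__ = [
    "ComparisonRow", "chi_square_test", "t_test_independent", "cramers_v",
    "responded_vs_ignored",
]


@dataclass(frozen=True)
class ComparisonRow:
    """One responded-vs-ignored comparison (one table row)."""

    variable: str
    responded_summary: dict
    ignored_summary: dict
    test: str                 # "chi_square" | "t_test"
    statistic: float
    p_value: float


def _clean_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("degenerate table: fewer than 2 non-empty rows/columns")
    return t


def chi_square_test(table) -> dict:
    """Pearson chi-square test of independence on an r×c count table.

    No continuity correction; empty margins are dropped first;
    ``df = (r−1)(c−1)``.  A table degenerate after dropping raises.
    """
    t = _clean_table(table)
    stat, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return {"statistic": float(stat), "df": int(dof), "p": float(p)}


def t_test_independent(group_a, group_b) -> dict:
    """Two-tailed pooled-variance (Student) two-sample t test.

    Each group is either a sequence of raw values or a ``(mean, sd, n)``
    summary triple.  Zero pooled variance with unequal means is degenerate
    and reported as ``p = 0`` with a flag.
    """
    def unpack(g):
        if isinstance(g, tuple) and len(g) == 3:
            return float(g[0]), float(g[1]), int(g[2])
        arr = np.asarray(g, dtype=float)
        if arr.size < 2:
            return float(arr.mean()) if arr.size else np.nan, np.nan, int(arr.size)
        return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)

    m1, s1, n1 = unpack(group_a)
    m2, s2, n2 = unpack(group_b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2)
    df = n1 + n2 - 2
    if pooled == 0:
        if m1 == m2:
            return {"t": 0.0, "df": df, "p": 1.0, "degenerate": False}
        return {"t": float(np.sign(m1 - m2)) * np.inf, "df": df, "p": 0.0,
                "degenerate": True}
    t = (m1 - m2) / np.sqrt(pooled * (1 / n1 + 1 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return {"t": float(t), "df": df, "p": float(p), "degenerate": False}


def cramers_v(table) -> float:
    """Cramér's V association measure: ``sqrt(χ² / (N·(min(r,c)−1)))``."""
    t = _clean_table(table)
    stat, _, _, _ = sps.chi2_contingency(t, correction=False)
    n = t.sum()
    return float(np.sqrt(stat / (n * (min(t.shape) - 1))))


_CATEGORICAL_VARS = ("weekday_weekend", "day_night", "gender",
                     "naloxone_carriage", "homeless", "employment",
                     "witnessed_band", "administered_band")
_NUMERIC_VARS = ("age", *HISTORY_COLUMNS, "distance_m")


def _alert_frame(log: AlertLog) -> pd.DataFrame:
    """Labeled per-alert analysis table over true-alarm alerts only."""
    hist = history_table(log)
    rows = []
    for alert in log.alerts:
        label = label_alert(log, alert)
        if label == "excluded":
            continue
        event, vol = log.event_of(alert), log.volunteer_of(alert)
        rows.append({
            "alert_id": alert.alert_id, "label": label,
            "final_status": alert.final_status,
            "weekday_weekend": event.weekday_weekend, "day_night": event.day_night,
            "gender": vol.gender, "naloxone_carriage": vol.naloxone_carriage,
            "homeless": "yes" if vol.homeless else "no",
            "employment": vol.employment, "witnessed_band": vol.witnessed_band,
            "administered_band": vol.administered_band,
            "age": vol.age,
            "distance_m": np.nan if alert.distance_m is None else float(alert.distance_m),
            **{c: int(hist.loc[alert.alert_id, c]) for c in HISTORY_COLUMNS},
        })
    return pd.DataFrame(rows)


def responded_vs_ignored(log: AlertLog) -> dict:
    """The responded-vs-ignored comparison table plus final-status shares.

    Returns ``{"rows": [ComparisonRow, ...], "status_shares": {...},
    "n_responded": int, "n_ignored": int}``.  Categorical variables use
    the chi-square test of independence, numeric variables the pooled t
    test; shares are over true-alarm alerts and sum to 1.
    """
    df = _alert_frame(log)
    for cls in ("responded", "ignored"):
        if df.empty or (df["label"] == cls).sum() == 0:
            raise ValueError(f"log has no {cls} alerts; both classes are required")

    resp = df[df["label"] == "responded"]
    ign = df[df["label"] == "ignored"]
    rows: list[ComparisonRow] = []
    for var in _CATEGORICAL_VARS:
        ct = pd.crosstab(df["label"], df[var])
        try:
            res = chi_square_test(ct.to_numpy())
        except ValueError:
            continue          # variable constant in this log: no test possible
        rows.append(ComparisonRow(
            variable=var,
            responded_summary=resp[var].value_counts().to_dict(),
            ignored_summary=ign[var].value_counts().to_dict(),
            test="chi_square", statistic=res["statistic"], p_value=res["p"]))
    for var in _NUMERIC_VARS:
        a = resp[var].dropna().to_numpy(dtype=float)
        b = ign[var].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            continue
        res = t_test_independent(a, b)
        rows.append(ComparisonRow(
            variable=var,
            responded_summary={"mean": float(a.mean()), "sd": float(a.std(ddof=1)),
                               "n": len(a)},
            ignored_summary={"mean": float(b.mean()), "sd": float(b.std(ddof=1)),
                             "n": len(b)},
            test="t_test", statistic=res["t"], p_value=res["p"]))

    shares = (df["final_status"].value_counts(normalize=True)
              .reindex(FINAL_STATUSES, fill_value=0.0).to_dict())
    return {"rows": rows, "status_shares": shares,
            "n_responded": len(resp), "n_ignored": len(ign)}
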