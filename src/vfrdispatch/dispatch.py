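"""Discrete-event simulation of the VFR dispatch loop.

The dispatcher ranks candidate volunteers by estimated time of arrival
(walking ETA = distance / speed), alerts an initial batch, and sends a
substitute alert whenever an alerted volunteer declines or stays silent
past a timeout (the study system waited 2 minutes).  The *predictive*
policy additionally consults a response-probability predictor at dispatch
time: every alerted candidate whose predicted probability falls below a
threshold triggers an immediate extra alert at t = 0 — the low-probability
volunteer is still alerted and can still respond; the policy only stops
*waiting* on them.

Policy comparisons use shared random numbers: each event's response
realization (who would answer, who would decline, with what latency) is
drawn once and replayed under both policies, so per-event differences are
pure policy effects.
"""
from __future__ import annotations

import heapq
import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import synthetic as syn

__all__ = [
    "PERFECT", "DispatchConfig", "Candidate", "CandidateRealization",
    "TraceAction", "DispatchTrace", "rank_by_eta", "realize_responses",
    "simulate_event_dispatch", "compare_policies", "substitute_delays",
    "scenarios_from_synthetic", "DispatchScenario", "write_traces",
]

#: Sentinel predictor with perfect knowledge of the response realization.
PERFECT = "perfect"

#: Share of answering volunteers who accept (go) rather than decline,
#: from the answered-status mix: en_route + on_scene + done.
DEFAULT_ACCEPT_GIVEN_ANSWER = 0.395

#: Mean of the exponential reaction-latency distribution, seconds.
DEFAULT_REACTION_MEAN_S = 30.0


@dataclass(frozen=True)
class DispatchConfig:
    timeout_s: float = 120.0          # silence tolerated before a substitute
    max_dispatched: int = 10
    initial_batch: int = 3
    walking_speed_mps: float = 1.4
    policy: str = "baseline"          # "baseline" | "predictive"
    predict_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.timeout_s <= 0:
            raise ValueError("timeout_s must be positive")
        if self.max_dispatched < 1:
            raise ValueError("max_dispatched must be at least 1")
        if self.policy not in ("baseline", "predictive"):
            raise ValueError(f"unknown policy {self.policy!r}")


@dataclass(frozen=True)
class Candidate:
    volunteer_id: str
    distance_m: float | None          # None = unknown, ranked last


@dataclass(frozen=True)
class CandidateRealization:
    """What one candidate would do if alerted: accept, decline, or stay silent."""

    accepts: bool
    declines: bool
    reaction_s: float                 # latency of the accept/decline; inf if silent

    @property
    def silent(self) -> bool:
        return not (self.accepts or self.declines)


@dataclass(frozen=True)
class TraceAction:
    t: float
    action: str       # alert | substitute_alert | accept | decline | timeout | arrival
    volunteer_id: str


@dataclass
class DispatchTrace:
    event_id: str
    timeline: list[TraceAction]
    time_to_first_accept: float | None
    alerts_sent: int
    substitutes_used: int

    def to_json(self) -> str:
        return json.dumps({
            "event_id": self.event_id,
            "timeline": [asdict(a) for a in self.timeline],
            "summary": {"time_to_first_accept": self.time_to_first_accept,
                        "alerts_sent": self.alerts_sent,
                        "substitutes_used": self.substitutes_used}})


def rank_by_eta(candidates: Sequence[Candidate],
                walking_speed_mps: float = 1.4) -> list[tuple[Candidate, float]]:
    """Order candidates by walking ETA, ascending.

    ETA = distance / speed.  Candidates with unknown distance rank last
    (infinite ETA); ties break lexicographically by volunteer id for
    determinism.
    """
    for c in candidates:
        if c.distance_m is not None and c.distance_m < 0:
            raise ValueError(f"negative distance for {c.volunteer_id}")
    etas = [(c, math.inf if c.distance_m is None else c.distance_m / walking_speed_mps)
            for c in candidates]
    return sorted(etas, key=lambda ce: (ce[1], ce[0].volunteer_id))


def realize_responses(candidates: Sequence[Candidate],
                      answer_probs: Mapping[str, float],
                      rng: np.random.Generator,
                      accept_given_answer: float = DEFAULT_ACCEPT_GIVEN_ANSWER,
                      reaction_mean_s: float = DEFAULT_REACTION_MEAN_S,
                      ) -> dict[str, CandidateRealization]:
    """Draw one shared response realization for an event.

    Each candidate answers with their model probability; answering
    candidates accept with probability ``accept_given_answer`` (otherwise
    decline), after an exponential reaction latency.  Silent candidates
    never react.
    """
    out: dict[str, CandidateRealization] = {}
    for c in sorted(candidates, key=lambda c: c.volunteer_id):
        answers = rng.random() < answer_probs[c.volunteer_id]
        if not answers:
            out[c.volunteer_id] = CandidateRealization(False, False, math.inf)
            continue
        accepts = rng.random() < accept_given_answer
        latency = float(rng.exponential(reaction_mean_s))
        out[c.volunteer_id] = CandidateRealization(accepts, not accepts, latency)
    return out


def _run_policy(event_id: str, ranked: Sequence[tuple[Candidate, float]],
                realization: Mapping[str, CandidateRealization],
                config: DispatchConfig,
                predicted: Mapping[str, float] | None) -> DispatchTrace:
    """Deterministic dispatch timeline for one fixed response realization."""
    timeline: list[TraceAction] = []
    heap: list[tuple[float, int, str, str]] = []     # (t, seq, kind, volunteer)
    seq = 0
    next_idx = 0
    alerts_sent = 0
    substitutes = 0
    triggered: set[str] = set()       # alerted volunteers that already caused a substitute
    reacted: set[str] = set()
    alerted: set[str] = set()
    first_accept: float | None = None

    def push(t: float, kind: str, vol: str) -> None:
        nonlocal seq
        heapq.heappush(heap, (t, seq, kind, vol))
        seq += 1

    def alert_next(t: float, substitute: bool) -> str | None:
        nonlocal next_idx, alerts_sent, substitutes
        if alerts_sent >= config.max_dispatched or next_idx >= len(ranked):
            return None
        cand, eta = ranked[next_idx]
        next_idx += 1
        alerts_sent += 1
        if substitute:
            substitutes += 1
        alerted.add(cand.volunteer_id)
        timeline.append(TraceAction(t, "substitute_alert" if substitute else "alert",
                                    cand.volunteer_id))
        real = realization[cand.volunteer_id]
        if not real.silent:
            push(t + real.reaction_s, "accept" if real.accepts else "decline",
                 cand.volunteer_id)
        push(t + config.timeout_s, "timeout", cand.volunteer_id)
        return cand.volunteer_id

    # t = 0: initial batch, then (predictive policy) the immediate-substitute
    # cascade for every alerted candidate predicted to ignore.
    batch = [alert_next(0.0, substitute=False)
             for _ in range(min(config.initial_batch, config.max_dispatched))]
    pending = [v for v in batch if v is not None]
    if config.policy == "predictive" and predicted is not None:
        while pending:
            vol = pending.pop(0)
            if predicted.get(vol, 1.0) < config.predict_threshold:
                triggered.add(vol)
                extra = alert_next(0.0, substitute=True)
                if extra is not None:
                    pending.append(extra)

    while heap and first_accept is None:
        t, _, kind, vol = heapq.heappop(heap)
        if kind == "accept":
            timeline.append(TraceAction(t, "accept", vol))
            reacted.add(vol)
            first_accept = t
        elif kind == "decline":
            timeline.append(TraceAction(t, "decline", vol))
            already = vol in reacted or vol in triggered
            reacted.add(vol)
            if not already:
                triggered.add(vol)
                alert_next(t, substitute=True)
        elif kind == "timeout":
            if vol in reacted or vol in triggered:
                continue                      # reacted in time, or already covered
            timeline.append(TraceAction(t, "timeout", vol))
            triggered.add(vol)
            alert_next(t, substitute=True)

    timeline.sort(key=lambda a: a.t)
    return DispatchTrace(event_id=event_id, timeline=timeline,
                         time_to_first_accept=first_accept,
                         alerts_sent=alerts_sent, substitutes_used=substitutes)


def simulate_event_dispatch(event_id: str, candidates: Sequence[Candidate],
                            response_model: Callable[..., Mapping[str, CandidateRealization]],
                            config: DispatchConfig, seed: int = 0,
                            answer_probs: Mapping[str, float] | None = None,
                            predicted: Mapping[str, float] | None = None,
                            ) -> DispatchTrace:
    """Simulate the dispatch of one event.

    ``response_model(candidates, answer_probs, rng)`` draws the response
    realization; :func:`realize_responses` is the stock model.  For the
    predictive policy ``predicted`` maps volunteer ids to predicted
    response probabilities (``PERFECT`` resolves them from the realization:
    1 for accepters, 0 otherwise).
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    rng = np.random.default_rng(np.random.SeedSequence(
        [seed & 0x7FFFFFFF, zlib.crc32(event_id.encode())]))
    realization = response_model(candidates, answer_probs or {}, rng)
    ranked = rank_by_eta(candidates, config.walking_speed_mps)
    pred = _resolve_predictions(predicted, realization)
    return _run_policy(event_id, ranked, realization, config, pred)


def _resolve_predictions(predicted, realization) -> Mapping[str, float] | None:
    if predicted == PERFECT:
        return {vid: (1.0 if real.accepts else 0.0)
                for vid, real in realization.items()}
    return predicted


@dataclass
class DispatchScenario:
    """One event's inputs: candidates and their true answer probabilities."""

    event_id: str
    candidates: list[Candidate]
    answer_probs: dict[str, float]


def scenarios_from_synthetic(config: syn.SyntheticConfig | None = None,
                             n_events: int = 200, seed: int = 0,
                             ) -> list[DispatchScenario]:
    """Build dispatch scenarios from the synthetic network generator.

    Each event's candidate pool, distances and true answer probabilities
    come from the generator's roster and propensity model (experience taken
    as zero: dispatch-time probabilities, not a running history).
    """
    cfg = config or syn.SyntheticConfig()
    cfg = syn.replace(cfg, n_events=n_events, seed=seed)
    roster = syn.sample_roster(cfg)
    events = syn.sample_events(cfg, roster)
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xD15A]))
    dist = cfg.distance_model
    all_ids = sorted(roster.volunteers)
    scenarios = []
    for event in events:
        pool = [vid for vid in all_ids if vid != event.signaler_id]
        chosen = rng.choice(pool, size=cfg.candidates_per_event, replace=False)
        cands, probs = [], {}
        for vid in map(str, chosen):
            d = min(float(rng.lognormal(dist.mu, dist.sigma)), dist.truncate_m)
            cands.append(Candidate(vid, d))
            probs[vid] = syn.answer_probability(cfg, roster, vid, d, answered_before=0)
        scenarios.append(DispatchScenario(event.event_id, cands, probs))
    return scenarios


def compare_policies(scenarios: Sequence[DispatchScenario],
                     config: DispatchConfig | None = None,
                     predictor=PERFECT, seed: int = 0) -> dict:
    """Run baseline and predictive dispatch on identical response realizations.

    ``predictor`` is :data:`PERFECT`, or a callable
    ``(event_id, candidate) -> probability``, or a mapping
    ``{event_id: {volunteer_id: probability}}``.  Returns per-policy
    summaries, paired per-event differences, and the traces.
    """
    if not scenarios:
        raise ValueError("need at least one scenario")
    base_cfg = config or DispatchConfig()
    cfg_base = DispatchConfig(**{**asdict(base_cfg), "policy": "baseline"})
    cfg_pred = DispatchConfig(**{**asdict(base_cfg), "policy": "predictive"})

    rows = []
    traces: dict[str, dict[str, DispatchTrace]] = {"baseline": {}, "predictive": {}}
    for sc in scenarios:
        rng = np.random.default_rng(np.random.SeedSequence(
            [seed & 0x7FFFFFFF, zlib.crc32(sc.event_id.encode())]))
        realization = realize_responses(sc.candidates, sc.answer_probs, rng)
        ranked = rank_by_eta(sc.candidates, base_cfg.walking_speed_mps)
        if predictor == PERFECT:
            pred = _resolve_predictions(PERFECT, realization)
        elif callable(predictor):
            pred = {c.volunteer_id: float(predictor(sc.event_id, c)) for c in sc.candidates}
        else:
            pred = dict(predictor[sc.event_id])
        tb = _run_policy(sc.event_id, ranked, realization, cfg_base, None)
        tp = _run_policy(sc.event_id, ranked, realization, cfg_pred, pred)
        traces["baseline"][sc.event_id] = tb
        traces["predictive"][sc.event_id] = tp
        rows.append({
            "event_id": sc.event_id,
            "t_accept_baseline": tb.time_to_first_accept,
            "t_accept_predictive": tp.time_to_first_accept,
            "alerts_baseline": tb.alerts_sent,
            "alerts_predictive": tp.alerts_sent,
            "subs_baseline": tb.substitutes_used,
            "subs_predictive": tp.substitutes_used,
        })
    events_df = pd.DataFrame(rows)

    def _summary(prefix: str) -> dict:
        t = events_df[f"t_accept_{prefix}"].astype(float)
        return {
            "mean_time_to_first_accept_s": float(t.mean()),
            "median_time_to_first_accept_s": float(t.median()),
            "n_no_accept": int(t.isna().sum()),
            "mean_alerts_sent": float(events_df[f"alerts_{prefix}"].mean()),
            "fraction_events_with_substitutes": float((events_df[f"subs_{prefix}"] > 0).mean()),
        }

    both = events_df.dropna(subset=["t_accept_baseline", "t_accept_predictive"])
    delta = both["t_accept_baseline"] - both["t_accept_predictive"]
    return {
        "baseline": _summary("baseline"),
        "predictive": _summary("predictive"),
        "paired": {
            "n_events": len(events_df),
            "n_paired_accepts": len(both),
            "mean_time_saving_s": float(delta.mean()) if len(both) else float("nan"),
            "median_time_saving_s": float(delta.median()) if len(both) else float("nan"),
            "max_time_regression_s": float((-delta).max()) if len(both) else float("nan"),
        },
        "events": events_df,
        "traces": traces,
    }


def substitute_delays(traces: Iterable[DispatchTrace],
                      bin_minutes: float = 2.0) -> pd.DataFrame:
    """Histogram of substitute-alert delays from event start, in minutes.

    Columns ``bin_start_min``, ``bin_end_min``, ``count``; bins of
    ``bin_minutes`` width from zero; counts sum to the total number of
    substitute alerts across the traces.
    """
    delays = [a.t / 60.0 for tr in traces for a in tr.timeline
              if a.action == "substitute_alert"]
    if not delays:
        return pd.DataFrame(columns=["bin_start_min", "bin_end_min", "count"])
    n_bins = int(math.floor(max(delays) / bin_minutes)) + 1
    edges = np.arange(n_bins + 1) * bin_minutes
    counts, _ = np.histogram(delays, bins=edges)
    return pd.DataFrame({"bin_start_min": edges[:-1], "bin_end_min": edges[1:],
                         "count": counts})


def write_traces(traces: Iterable[DispatchTrace], path) -> None:
    """Serialize traces as JSON-lines, one trace per event."""
    with open(path, "w", encoding="utf-8") as fh:
        for tr in traces:
            fh.write(tr.to_json() + "\n")
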