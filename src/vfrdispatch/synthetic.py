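"""Synthetic VFR alert-log generator.

The real trial log (112 volunteers, 188 overdose events, 993 alerts) is not
public, so analyses here run on synthetic logs that reproduce the
*statistical structure* the pipeline exploits:

* **persistent individual propensity** — each volunteer carries a fixed
  latent random intercept on the log-odds scale, so past response behavior
  predicts future behavior;
* **experience feedback** — answering alerts raises the propensity through
  a damped ``log(1 + previous answered alerts)`` term;
* **demographic effects** — male and unemployed volunteers respond more,
  part-time employed less, older slightly more (matching the direction of
  the observed responded-vs-ignored differences);
* **context marginals** — weekday/weekend and day/night shares, false-alarm
  flags, signaler identity, and log-normal alert distances with an
  event-level missingness rate, all calibrated to the study's descriptive
  tables by default.

Randomness is fully deterministic under a fixed seed: every operation draws
from its own named substream (``roster``, ``events``, ``responses``) split
off the master seed, so the roster is bit-identical whether or not events
are generated afterwards.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict, replace
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml
from scipy.special import expit

from .data_model import (Alert, AlertLog, Event, Volunteer, ANSWERED_STATUSES,
                         BANDS, CARRIAGE, EMPLOYMENT, GENDERS)

__all__ = [
    "PropensityCoefficients", "DistanceModel", "DemographicsMix",
    "SyntheticConfig", "LatentPropensity", "Roster",
    "sample_roster", "sample_events", "simulate_responses",
    "generate_alert_log",
]

# Monday 2019-01-07 00:00:00 UTC — base of the simulated 52-week study year.
_BASE_EPOCH = int(datetime(2019, 1, 7, tzinfo=timezone.utc).timestamp())
_WEEKS = 52


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named substream: integer-state RNG keyed by (seed, crc32(name))."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())]))


@dataclass(frozen=True)
class PropensityCoefficients:
    """Log-odds model of a volunteer answering one alert.

    ``logit(p) = intercept + u_v + b_experience*log(1+answered_before)
    + b_distance_per_km*distance_km + b_male + b_unemployed|b_part_time
    + b_age_per_decade*(age-40)/10`` with ``u_v ~ N(0, sd_volunteer_intercept²)``
    drawn once per volunteer.
    """

    intercept: float = -1.1
    sd_volunteer_intercept: float = 1.5
    b_experience: float = 0.35
    b_distance_per_km: float = -0.08
    b_male: float = 0.30
    b_unemployed: float = 0.40
    b_part_time: float = -0.40
    b_age_per_decade: float = 0.15


@dataclass(frozen=True)
class DistanceModel:
    """Log-normal alert distance (meters), truncated, with event-level missingness.

    Defaults reproduce the study's mean 3326 m / SD 2784 m and the 13.8%
    of events with no distance recorded.
    """

    mu: float = 7.8441           # log-scale location for mean 3326 m
    sigma: float = 0.7287        # log-scale spread for SD 2784 m
    truncate_m: float = 20_000.0
    p_missing_event: float = 0.138


def _bands(le20: float, mid: float, gt40: float) -> dict[str, float]:
    return {BANDS[0]: le20, BANDS[1]: mid, BANDS[2]: gt40}


@dataclass(frozen=True)
class DemographicsMix:
    """Marginal distributions of volunteer attributes (study roster defaults)."""

    gender: dict[str, float] = field(default_factory=lambda: {
        "male": 0.44, "female": 0.55, "intersex": 0.01})
    homeless: float = 22 / 80            # P(homeless)
    employment: dict[str, float] = field(default_factory=lambda: {
        "part_time": 11 / 80, "full_time": 18 / 80, "unemployed": 51 / 80})
    naloxone_carriage: dict[str, float] = field(default_factory=lambda: {
        "all_the_time": 36 / 80, "often": 22 / 80, "sometimes": 10 / 80,
        "seldom": 2 / 80, "never": 10 / 80})
    witnessed: dict[str, float] = field(default_factory=lambda: _bands(0.60, 0.25, 0.15))
    administered: dict[str, float] = field(default_factory=lambda: _bands(61 / 75, 7 / 75, 7 / 75))
    age_mean: float = 40.31
    age_sd: float = 10.41
    age_min: int = 18


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generator configuration; defaults emulate the study conditions."""

    n_volunteers: int = 112
    n_events: int = 188
    p_false_alarm: float = 0.30
    p_weekend: float = 0.277
    p_night: float = 0.293
    distance_model: DistanceModel = field(default_factory=DistanceModel)
    candidates_per_event: int = 5
    propensity_model: PropensityCoefficients = field(default_factory=PropensityCoefficients)
    answered_status_mix: dict[str, float] = field(default_factory=lambda: {
        "no_go": 0.58, "en_route": 0.13, "on_scene": 0.065,
        "done": 0.20, "canceled_dispatch": 0.025})
    demographics_mix: DemographicsMix = field(default_factory=DemographicsMix)
    seed: int = 0

    def validate(self) -> None:
        for name, p in (("p_false_alarm", self.p_false_alarm),
                        ("p_weekend", self.p_weekend), ("p_night", self.p_night)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.n_volunteers < 0 or self.n_events < 0:
            raise ValueError("counts must be non-negative")
        if self.n_events > 0 and self.n_volunteers < self.candidates_per_event + 1:
            raise ValueError("need n_volunteers >= candidates_per_event + 1 "
                             "(the signaler is never alerted)")
        if set(self.answered_status_mix) - set(ANSWERED_STATUSES):
            raise ValueError("answered_status_mix has unknown statuses")
        _check_mix("answered_status_mix", self.answered_status_mix)
        mix = self.demographics_mix
        _check_mix("gender", mix.gender)
        _check_mix("employment", mix.employment)
        _check_mix("naloxone_carriage", mix.naloxone_carriage)
        _check_mix("witnessed", mix.witnessed)
        _check_mix("administered", mix.administered)
        if not 0.0 <= mix.homeless <= 1.0:
            raise ValueError("homeless probability outside [0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        """Load a config from YAML or JSON mirroring the field names."""
        text = Path(path).read_text(encoding="utf-8")
        raw = yaml.safe_load(text) or {}
        for key, sub in (("distance_model", DistanceModel),
                         ("propensity_model", PropensityCoefficients),
                         ("demographics_mix", DemographicsMix)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def _check_mix(name: str, mix: dict[str, float]) -> None:
    if any(p < 0 for p in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities must be non-negative and sum to 1")


@dataclass(frozen=True)
class LatentPropensity:
    """Per-volunteer random intercept (log-odds units), fixed for the whole log."""

    volunteer_id: str
    random_intercept: float


@dataclass
class Roster:
    """Sampled volunteers plus their latent propensities."""

    volunteers: dict[str, Volunteer]
    propensities: dict[str, LatentPropensity]

    def __len__(self) -> int:
        return len(self.volunteers)


def _choice(rng: np.random.Generator, mix: dict[str, float], size: int) -> np.ndarray:
    keys = list(mix)
    return rng.choice(keys, size=size, p=[mix[k] for k in keys])


def sample_roster(config: SyntheticConfig, seed: int | None = None) -> Roster:
    """Draw the volunteer roster and each volunteer's latent propensity.

    Demographics are drawn independently from ``config.demographics_mix``;
    ages are normal, truncated below at ``age_min``, rounded to years.
    """
    config.validate()
    rng = _substream(config.seed if seed is None else seed, "roster")
    n = config.n_volunteers
    mix = config.demographics_mix
    ids = [f"V{i + 1:04d}" for i in range(n)]

    ages = rng.normal(mix.age_mean, mix.age_sd, size=n)
    while np.any(ages < mix.age_min):      # truncated normal by resampling
        bad = ages < mix.age_min
        ages[bad] = rng.normal(mix.age_mean, mix.age_sd, size=int(bad.sum()))
    genders = _choice(rng, mix.gender, n)
    homeless = rng.random(n) < mix.homeless
    employment = _choice(rng, mix.employment, n)
    carriage = _choice(rng, mix.naloxone_carriage, n)
    witnessed = _choice(rng, mix.witnessed, n)
    administered = _choice(rng, mix.administered, n)
    intercepts = rng.normal(0.0, config.propensity_model.sd_volunteer_intercept, size=n)

    volunteers = {
        vid: Volunteer(vid, int(round(ages[i])), str(genders[i]), bool(homeless[i]),
                       str(employment[i]), str(carriage[i]), str(witnessed[i]),
                       str(administered[i]))
        for i, vid in enumerate(ids)
    }
    propensities = {vid: LatentPropensity(vid, float(intercepts[i]))
                    for i, vid in enumerate(ids)}
    return Roster(volunteers, propensities)


def sample_events(config: SyntheticConfig, roster: Roster,
                  seed: int | None = None) -> list[Event]:
    """Draw events over a 52-week horizon.

    Weekend and night flags are Bernoulli draws; a concrete timestamp is
    then placed inside the matching calendar stratum (Sat/Sun vs Mon-Fri,
    06:00-17:59 vs the complement), so the derived context flags agree with
    the sampled ones by construction.  The signaler is uniform over the
    roster and the false-alarm flag is Bernoulli.
    """
    config.validate()
    if config.n_events > 0 and len(roster) == 0:
        raise ValueError("cannot sample events from an empty roster")
    rng = _substream(config.seed if seed is None else seed, "events")
    n = config.n_events

    weekend = rng.random(n) < config.p_weekend
    night = rng.random(n) < config.p_night
    week = rng.integers(0, _WEEKS, size=n)
    day = np.where(weekend, rng.integers(5, 7, size=n), rng.integers(0, 5, size=n))
    # Day hours are 06..17; night hours are 18..23 followed by 00..05.
    hour = np.where(night, (18 + rng.integers(0, 12, size=n)) % 24,
                    rng.integers(6, 18, size=n))
    minute = rng.integers(0, 60, size=n)
    second = rng.integers(0, 60, size=n)
    ts = (_BASE_EPOCH + ((week * 7 + day) * 24 + hour) * 3600
          + minute * 60 + second)

    false_alarm = rng.random(n) < config.p_false_alarm
    signalers = rng.choice(sorted(roster.volunteers), size=n) if n else np.array([])

    order = np.argsort(ts, kind="stable")
    return [Event(f"E{rank + 1:05d}", int(ts[i]), bool(false_alarm[i]), str(signalers[i]))
            for rank, i in enumerate(order)]


def simulate_responses(config: SyntheticConfig, roster: Roster,
                       events: list[Event], seed: int | None = None) -> AlertLog:
    """Alert candidates per event and draw answers from the propensity model.

    For each event (in time order) ``candidates_per_event`` distinct
    non-signaler volunteers are alerted, with log-normal distances (set
    missing for a ``p_missing_event`` share of events).  The answer
    probability follows :class:`PropensityCoefficients`; a missing distance
    contributes its model mean.  Answered alerts draw a final status from
    ``answered_status_mix``; ignored alerts get ``no_answer``.  Alerts are
    emitted in event order so history features are well defined.
    """
    config.validate()
    if events and config.candidates_per_event > len(roster) - 1:
        raise ValueError("candidates_per_event exceeds available non-signalers")
    rng = _substream(config.seed if seed is None else seed, "responses")
    coef = config.propensity_model
    dist = config.distance_model
    mean_distance_km = float(np.exp(dist.mu + dist.sigma ** 2 / 2)) / 1000.0
    status_keys = list(config.answered_status_mix)
    status_p = [config.answered_status_mix[k] for k in status_keys]
    all_ids = sorted(roster.volunteers)

    answered_before: dict[str, int] = {vid: 0 for vid in all_ids}
    alerts: list[Alert] = []
    counter = 0
    for event in sorted(events, key=lambda e: (e.timestamp, e.event_id)):
        pool = [vid for vid in all_ids if vid != event.signaler_id]
        chosen = rng.choice(pool, size=config.candidates_per_event, replace=False)
        event_distance_missing = rng.random() < dist.p_missing_event
        for k, vid in enumerate(chosen):
            vid = str(vid)
            counter += 1
            if event_distance_missing:
                distance: float | None = None
                distance_km = mean_distance_km
            else:
                d = float(rng.lognormal(dist.mu, dist.sigma))
                distance = min(d, dist.truncate_m)
                distance_km = distance / 1000.0
            v = roster.volunteers[vid]
            eta = (coef.intercept
                   + roster.propensities[vid].random_intercept
                   + coef.b_experience * np.log1p(answered_before[vid])
                   + coef.b_distance_per_km * distance_km
                   + coef.b_male * (v.gender == "male")
                   + coef.b_unemployed * (v.employment == "unemployed")
                   + coef.b_part_time * (v.employment == "part_time")
                   + coef.b_age_per_decade * (v.age - 40) / 10.0)
            p = float(expit(eta))
            answered = bool(rng.random() < p)
            if answered:
                status = str(rng.choice(status_keys, p=status_p))
                answered_before[vid] += 1
            else:
                status = "no_answer"
            alerts.append(Alert(f"A{counter:06d}", event.event_id, vid,
                                event.timestamp + k,
                                None if distance is None else round(distance, 1),
                                status))
    return AlertLog(volunteers=dict(roster.volunteers),
                    events={e.event_id: e for e in events},
                    alerts=alerts)


def generate_alert_log(config: SyntheticConfig | None = None,
                       seed: int | None = None) -> AlertLog:
    """End-to-end convenience: roster → events → responses under one seed."""
    config = config or SyntheticConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    roster = sample_roster(config)
    events = sample_events(config, roster)
    return simulate_responses(config, roster, events)


def answer_probability(config: SyntheticConfig, roster: Roster,
                       volunteer_id: str, distance_m: float | None,
                       answered_before: int) -> float:
    """The generator's analytic per-alert answer probability (for oracles)."""
    coef = config.propensity_model
    dist = config.distance_model
    if distance_m is None:
        distance_km = float(np.exp(dist.mu + dist.sigma ** 2 / 2)) / 1000.0
    else:
        distance_km = distance_m / 1000.0
    v = roster.volunteers[volunteer_id]
    eta = (coef.intercept
           + roster.propensities[volunteer_id].random_intercept
           + coef.b_experience * np.log1p(answered_before)
           + coef.b_distance_per_km * distance_km
           + coef.b_male * (v.gender == "male")
           + coef.b_unemployed * (v.employment == "unemployed")
           + coef.b_part_time * (v.employment == "part_time")
           + coef.b_age_per_decade * (v.age - 40) / 10.0)
    return float(expit(eta))
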