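# Methods

This note documents the models, defaults and numerical choices behind
`vfrdispatch`, and what the synthetic experiments do and do not show.

## The problem

A volunteer first responder (VFR) network alerts nearby lay volunteers to
an emergency signaled by a peer.  The dispatcher observes, per alert, the
event context (weekday/weekend, day/night, distance to the scene) and the
volunteer's record, and must decide whom to alert and how long to wait
before alerting substitutes.  The package treats two coupled questions:
can an alert's outcome (responded vs ignored) be predicted from the data a
dispatch app already stores, and how much waiting time does integrating
such predictions into substitute dispatch remove.

## Data model and conventions

Timestamps are integer seconds UTC.  "Day" is 06:00–17:59 on the UTC
clock and "weekend" is Saturday/Sunday; the emulated study never published
its boundaries, so these are package conventions, kept in named module
constants.  Distances are scalar meters; a missing distance is encoded as
an empty CSV field and `None`/`NaN` in memory, never `0`, because zero is
a legitimate distance.  An alert's *final status* is one of `no_answer`,
`no_go`, `en_route`, `on_scene`, `done`, `canceled_dispatch`; every status
except `no_answer` counts as an *answer* (the volunteer engaged with the
alert, even to decline).  A signaler never receives an alert for their own
event, and the log keeps at most one alert per (event, responder) pair;
re-alerting is flagged by the validator rather than modeled.

## Synthetic network generator

The generator produces alert logs with the statistical structure the
analysis assumes, under one master seed with a named substream per
operation (`roster`, `events`, `responses`), so every artifact is
bit-reproducible and the roster does not change when more events are
drawn.

Per-alert answer probability:

```
logit p = β₀ + u_v + β_exp·log(1 + answered_before_v)
          + β_dist·distance_km + β_male·male + β_unemp·unemployed
          + β_part·part_time + β_age·(age − 40)/10,     u_v ~ N(0, σ_u²)
```

Defaults: `β₀ = −1.1`, `σ_u = 1.5`, `β_exp = 0.35`, `β_dist = −0.08/km`,
`β_male = 0.30`, `β_unemp = 0.40`, `β_part = −0.40`, `β_age = 0.15` per
decade.  They were chosen to satisfy three qualitative calibration targets
at once: a marginal answer rate near 0.40 (the emulated study's 394/993),
persistent individual propensity as the dominant source of variation (its
principal finding), and the observed effect directions (male and
unemployed volunteers answer more, part-time employed less, older
slightly more).  The experience term uses `log(1 + answered)` because only
a monotone association is documented; the damping prevents runaway
rich-get-richer feedback over a simulated year.  A missing distance
contributes its log-normal model mean (≈ 3.3 km) to the linear predictor.

Other defaults: 112 volunteers, 188 events, 5 candidates per event
(≈ 5.3 alerts/event in the emulated study), weekend share 0.277, night
share 0.293, alert distances log-normal with mean 3326 m / SD 2784 m
truncated at 20 km, distance missing for 13.8% of events (at the event
level, mirroring how the data were lost), and an answered-status mix of
no_go 0.58, en_route 0.13, on_scene 0.065, done 0.20, canceled 0.025
(the study's final-status shares renormalized over answered alerts).
The false-alarm share of events is not published anywhere; the default
0.30 is inferred from the ratio of mean previous false alerts to mean
previous alerts (≈ 7/22.6) in the published history-feature table.
Candidate selection is uniform over non-signalers: the real system used
proximity, but candidate identity is irrelevant to the feature/label
structure, and proximity is modeled where it matters, in the dispatch
simulator.

Event timestamps are placed by first drawing the weekend and night flags
and then sampling a concrete second inside the matching calendar stratum
of a 52-week year, so derived context features always agree with the
sampled marginals.

**What the generator does not emulate:** spatial structure (distances are
i.i.d. draws, not geography), diurnal or seasonal intensity beyond two
Bernoulli flags, volunteer churn, correlated demographics (attributes are
drawn independently; the real roster showed gender–homelessness and
experience–experience correlations), and any drift in individual
propensity.  Passing tests therefore show that the *pipeline* recovers
structure that is present, not that real VFR data contain exactly this
structure.

## History features and the frequent-responder indicator

All seven counters aggregate alerts to the same responder that are
strictly earlier in the global `(alert_time, alert_id)` order — appending
future alerts can never change an existing feature (causality, property-
tested).  History includes alerts of false-alarm events even though those
alerts are excluded as classification instances: "previous false alerts"
is itself a feature, which is only computable if history spans false
alarms.  A *response* is any non-`no_answer` status, consistent with the
label; this is a package decision (the emulated study says only "response
rate") and is deliberately kept in one place.

The frequent-responder indicator is `false` below 6 alerts and otherwise
compares the response rate against 50% (6–10 alerts), 40% (11–20), 30%
(21–30), 25% (≥31).  It is recomputed from scratch at every alert
(dynamic), never frozen at training time.

## Classifier

The tree is in the C4.5 lineage: greedy univariate partitioning by gain
ratio among attributes whose information gain reaches the mean of the
positive gains; numeric thresholds at midpoints between observed values,
the best chosen by information gain; multiway splits on categorical
attributes.  Instances missing the split attribute are distributed
fractionally over branches in proportion to known branch weights, during
both scoring and routing (missing distance is *handled*, not imputed).
When no attribute has positive gain but the node is impure and a
structurally valid split exists, a zero-gain split is allowed — this is
what lets the tree represent parity-style interactions (XOR) — and
pruning removes such splits when they did not help.  Default
hyperparameters are `min_leaf = 2` and pruning confidence `0.25`
(the common defaults for this family); pruning is pessimistic-error
pruning using the Clopper–Pearson upper confidence limit of the leaf
error rate (which reduces to the classic `1 − cf^(1/N)` at zero errors);
subtree raising is not implemented, a documented simplification.  Leaf
probabilities are Laplace-smoothed, `(k_c + 1)/(n + K)`, aggregated over
fractionally reached leaves; prediction ties resolve to `ignored`,
because falsely predicting a response delays a substitute while the
converse merely over-dispatches.

Evaluation: stratified 10-fold CV (stratification is a package choice to
stabilize per-class recall at n ≈ 1000) or a chronological split that
trains on the earliest `floor(0.669·n)` instances.  The chronological
protocol refuses input whose `alert_time` column is not non-decreasing:
with dynamically recomputed behavioral features, row order is part of the
data contract, and shuffling would leak future behavior.  Whether the
emulated study's own 66.9/33.1 split was strictly chronological is not
documented; chronological is implemented as the only leakage-safe
reading.  Reference learners (native Newton logistic regression with
tolerance 1e-8 and ≤100 iterations; scikit-learn random forest and MLP
behind a thin adapter) share a one-hot/mean-impute encoding.

## Dispatch simulator

Candidates are ranked by walking ETA (`distance / 1.4 m/s`), unknown
distances last, ties by volunteer id.  The baseline policy alerts an
initial batch (default 3), then alerts the next candidate whenever an
alerted volunteer declines or stays silent for `timeout_s` (default
120 s), up to `max_dispatched` (default 10; batch size and cap are
package defaults — the emulated system published only the 2-minute
timeout, and over-dispatch is known to erode willingness to respond).
The timeout runs per volunteer; each alerted volunteer triggers at most
one substitute (decline or timeout, whichever first).  The predictive
policy keeps all of that and additionally, at dispatch time (t = 0),
alerts an immediate substitute for every alerted candidate whose
predicted response probability is below the threshold, cascading until
the cap; predicted ignorers are still alerted and can still respond.
With threshold 0 the policy is bit-identical to baseline (tested).

Response realizations draw: answer with the propensity-model probability;
answering volunteers accept with probability 0.395 (the accept share of
answered statuses: en_route + on_scene + done) else decline; reaction
latencies are exponential with mean 30 s (no latency distribution is
published; silent ignorers never react).  Policy comparisons replay the
identical realization under both policies (shared random numbers), which
makes the perfect-predictor dominance property exact per event, not just
on average.

## Statistics

Categorical responded-vs-ignored comparisons use Pearson's chi-square
without continuity correction; numeric ones use the pooled-variance
two-tailed t test; effect size for categorical association is Cramér's V.
These exact conventions reproduce the published p-values from the
published count tables (weekday .49, day/night .44, sex .05, homelessness
.18, age .003), which fixes the otherwise ambiguous test variants.  No
multiple-testing adjustment is applied, matching the emulated analysis.
Degenerate cases are reported as data, not errors: zero-denominator
metrics are flagged 0; a zero-pooled-variance t test with unequal means
reports p = 0 with a degenerate flag.

## Problem sizes and numerical notes

The test suite and the acceptance script use study-scale logs (188–400
events; 940–2000 alerts), 10 generator replicates for the
model-comparison experiment, and 200 simulated dispatch events; these
sizes make every qualitative conclusion stable across seeds while keeping
a full run in well under a minute each.  Entropies are computed in bits
with `x log x = 0` at zero; split scores treat gains below 1e-12 as zero;
fractional instance weights below 1e-6 are dropped during tree induction
to bound the blow-up from repeated missing-value splits.

## Known limitations

* The tree omits subtree raising, so very deep trees may prune less
  aggressively than Weka's J48.
* The generator's independence assumptions (demographics, distances)
  understate real-world confounding; with the study-sized 112-volunteer
  roster, demographic effect directions can be masked by random-intercept
  luck in any single replicate — tests for effect directions therefore
  use larger rosters.
* The dispatch simulator models no EMS co-dispatch, no travel after
  acceptance (arrival modeling stops at the accept), and no behavioral
  feedback from over-alerting.
* Kendall's τ for ordinal table rows and the roster correlation matrix
  of the emulated study are out of scope.
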