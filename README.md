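# vfrdispatch

Predictive dispatch analysis for **volunteer first responder (VFR)
networks** — communities of lay volunteers (here modeled on an
opioid-overdose response community whose members carry naloxone) who are
alerted through an app when a peer signals an emergency nearby.

Location-based dispatchers pick the volunteers with the shortest estimated
time of arrival and then *wait* — in the system this package models, two
minutes of silence before a substitute is alerted.  Most alerts are
ignored, so much of the response time is spent waiting on people who were
never going to answer.  This package implements the full analysis loop for
doing better:

1. **Alert-log data model** (`vfrdispatch.data_model`) — volunteers,
   events, alerts with final statuses (`no_answer`, `no_go`, `en_route`,
   `on_scene`, `done`, `canceled_dispatch`), strict CSV round-tripping and
   invariant validation.
2. **Synthetic network generator** (`vfrdispatch.synthetic`) — alert logs
   with the structure the analysis exploits: each volunteer `v` answers an
   alert with probability

   `logit p = β₀ + u_v + β_exp·log(1+answered_before) + β_dist·d_km + x_vᵀβ,  u_v ~ N(0, σ_u²)`

   i.e. a *persistent* random intercept (past behavior predicts future
   behavior), experience feedback, and demographic effects; marginals
   (weekday/night shares, distances, demographics, status mix) are
   calibrated to the study population the package emulates.
3. **Behavioral features** (`vfrdispatch.features`) — seven leakage-free
   cumulative history counters per alert, the dynamic **frequent
   responder** indicator (≥6 alerts and a response rate over a threshold
   that relaxes from 50% to 25% as alerts accumulate), labels, and the
   four model configurations: context only (1), context + history (2),
   context + demographics (3), context + demographics + indicator (4).
4. **Classifier** (`vfrdispatch.classifiers`) — a C4.5-style univariate
   decision tree: gain-ratio attribute selection with mean-gain gating,
   midpoint thresholds for numeric attributes, fractional routing of
   missing values, pessimistic-error pruning, Laplace-smoothed leaf
   probabilities.  Evaluation by stratified 10-fold CV or — required for
   the dynamic indicator — a chronological 66.9%/33.1% split.  A native
   Newton logistic regression and scikit-learn adapters (random forest,
   multilayer perceptron) serve as reference learners.
5. **Dispatch simulator** (`vfrdispatch.dispatch`) — discrete-event
   simulation of the dispatch loop (ETA ranking, 120 s timeout, decline-
   and timeout-triggered substitutes) and of **predictive dispatch**:
   an immediate substitute for every alerted volunteer predicted to
   ignore.  Policies are compared with shared random numbers.
6. **Statistics** (`vfrdispatch.stats`) — chi-square tests of
   independence, pooled t tests, Cramér's V, and the responded-vs-ignored
   comparison table.

## Worked example

```python
from vfrdispatch import generate_alert_log
from vfrdispatch.classifiers import C45Learner, ChronoSplit, CV10, c45_fit, evaluate
from vfrdispatch.features import build_instances

log = generate_alert_log(seed=1)          # 112 volunteers, 188 events, 940 alerts
df4 = build_instances(log, 4)             # 590 true-alarm instances
report = evaluate(df4, C45Learner(), ChronoSplit(train_frac=0.669))
print(report.accuracy, report.per_class["responded"]["recall"])
```

Running `python examples/03_train_and_evaluate.py` prints:

```
model  protocol      accuracy  recall(responded)  recall(ignored)
  1    cv10          0.569     0.218              0.801
  2    cv10          0.676     0.483              0.803
  3    cv10          0.636     0.491              0.730
  4    chrono_split  0.668     0.566              0.733

model-4 tree: root split on 'frequent_responder', 49 leaves
```

Read this as the study's qualitative finding reproduced on synthetic data:
with event context alone (model 1) responded alerts are nearly
unpredictable; adding behavioral history (models 2 and 4) lifts
responded-class recall sharply, and the frequent-responder indicator is
the most informative single variable (it is the tree's root split).
`python examples/04_dispatch_simulation.py` then shows what that buys the
dispatcher: with a perfect response predictor and shared randomness, mean
time to first accepted alert drops from 53.9 s to 29.4 s and is never
worse on any event.

The other examples (`examples/01…05`) generate logs, inspect history
features, and print the responded-vs-ignored statistics table.

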