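"""Gain-ratio tree: split scoring vs a brute-force entropy oracle, fitting,
prediction with fractional missing-value routing, metrics, and protocols."""
import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from vfrdispatch.classifiers import (C45Learner, C45Params, ChronoSplit, CV10,
                                     EvalReport, LogisticLearner, c45_fit,
                                     c45_predict, chrono_split_sizes,
                                     confusion_metrics, cv_folds, evaluate,
                                     gain_ratio, majority_learner)
from vfrdispatch.features import build_instances


# ---------------------------------------------------------------------------
# independent brute-force entropy oracle

def _H(counter: Counter) -> float:
    n = sum(counter.values())
    return -sum(k / n * math.log2(k / n) for k in counter.values() if k)


def _branch_entropy(branches: list[tuple[Counter, float]], missing: Counter,
                    total_n: int) -> tuple[float, float]:
    """(conditional entropy, split info) distributing missing fractionally."""
    wk = sum(sum(c.values()) for c, _ in branches)
    cond = si = 0.0
    for counts, _ in branches:
        frac = sum(counts.values()) / wk
        full = Counter(counts)
        for lab, m in missing.items():
            full[lab] += frac * m
        wb = sum(full.values()) / total_n
        cond += wb * _H(full)
        if wb > 0:
            si -= wb * math.log2(wb)
    return cond, si


def oracle_gain(rows: list[tuple[object, str]]):
    """Enumerate branches / thresholds straight from the definitions."""
    total = Counter(lab for _, lab in rows)
    n = len(rows)
    known = [(v, l) for v, l in rows if v is not None]
    missing = Counter(l for v, l in rows if v is None)
    if len(total) < 2 or n < 2 or not known:
        return {"info_gain": 0.0, "split_info": 0.0, "gain_ratio": 0.0,
                "best_threshold": None}
    h_all = _H(total)
    if isinstance(known[0][0], str):
        values = sorted({v for v, _ in known})
        if len(values) < 2:
            return {"info_gain": 0.0, "split_info": 0.0, "gain_ratio": 0.0}
        branches = [(Counter(l for v, l in known if v == val), 0.0) for val in values]
        cond, si = _branch_entropy(branches, missing, n)
        ig = h_all - cond
        return {"info_gain": ig, "split_info": si,
                "gain_ratio": ig / si if si > 1e-12 else 0.0}
    distinct = sorted({v for v, _ in known})
    best = {"info_gain": 0.0, "split_info": 0.0, "gain_ratio": 0.0,
            "best_threshold": None}
    for lo, hi in zip(distinct, distinct[1:]):
        thr = (lo + hi) / 2
        left = Counter(l for v, l in known if v <= thr)
        right = Counter(l for v, l in known if v > thr)
        cond, si = _branch_entropy([(left, 0.0), (right, 0.0)], missing, n)
        ig = h_all - cond
        if ig > best["info_gain"] + 1e-12:
            best = {"info_gain": ig, "split_info": si,
                    "gain_ratio": ig / si if si > 1e-12 else 0.0,
                    "best_threshold": thr}
    return best


class TestGainRatio:
    def test_perfect_binary_split_is_one_bit(self):
        df = pd.DataFrame({"x": ["a", "a", "b", "b"],
                           "label": ["p", "p", "q", "q"]})
        out = gain_ratio(df, "x")
        assert out == pytest.approx({"info_gain": 1.0, "split_info": 1.0,
                                     "gain_ratio": 1.0})

    def test_independent_attribute_has_zero_gain(self):
        df = pd.DataFrame({"x": ["a", "b", "a", "b"],
                           "label": ["p", "p", "q", "q"]})
        assert gain_ratio(df, "x")["info_gain"] == pytest.approx(0.0)

    def test_single_label_gives_zero(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "label": ["p", "p", "p"]})
        assert gain_ratio(df, "x")["info_gain"] == 0.0

    def test_unknown_attribute_rejected(self):
        df = pd.DataFrame({"x": ["a"], "label": ["p"]})
        with pytest.raises(KeyError):
            gain_ratio(df, "zzz")

    @pytest.mark.parametrize("kind", ["categorical", "numeric"])
    def test_matches_bruteforce_oracle_on_random_datasets(self, kind):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            labels = rng.choice(["p", "q"], size=n)
            if kind == "categorical":
                vals = [None if rng.random() < 0.15 else str(v)
                        for v in rng.choice(list("abc"), size=n)]
                col = pd.Series(vals, dtype=object)
            else:
                vals = [None if rng.random() < 0.15 else float(v)
                        for v in rng.integers(0, 5, size=n)]
                col = pd.Series(vals, dtype=float)
            df = pd.DataFrame({"x": col, "label": labels})
            got = gain_ratio(df, "x")
            rows = [(None if (v is None or (isinstance(v, float) and np.isnan(v)))
                     else v, l) for v, l in zip(df["x"], labels)]
            want = oracle_gain(rows)
            assert got["info_gain"] == pytest.approx(want["info_gain"], abs=1e-9)
            if want["info_gain"] > 1e-9:
                # at zero gain the reported split_info depends on an
                # arbitrary threshold tie-break, so compare only then
                assert got["split_info"] == pytest.approx(want["split_info"], abs=1e-9)
            assert got["gain_ratio"] == pytest.approx(want["gain_ratio"], abs=1e-9)


def xor_frame() -> pd.DataFrame:
    return pd.DataFrame({
        "x1": ["0", "0", "1", "1"],
        "x2": ["0", "1", "0", "1"],
        "label": ["ignored", "responded", "responded", "ignored"],
    })


class TestFit:
    def test_single_class_gives_one_leaf(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "label": ["p", "p"]})
        tree = c45_fit(df)
        assert tree.root.is_leaf and tree.root.class_counts.sum() == 2

    def test_xor_learned_exactly_without_pruning(self):
        df = xor_frame()
        tree = c45_fit(df, C45Params(min_leaf=1, prune=False))
        preds = [c45_predict(tree, row).class_
                 for row in df[["x1", "x2"]].to_dict("records")]
        assert preds == list(df["label"])
        assert tree.root.depth() == 2

    def test_min_leaf_larger_than_n_gives_majority_leaf(self):
        df = pd.DataFrame({"x": ["a", "a", "b"], "label": ["p", "p", "q"]})
        tree = c45_fit(df, C45Params(min_leaf=10, prune=False))
        assert tree.root.is_leaf
        assert c45_predict(tree, {"x": "b"}).class_ == "p"

    def test_empty_instances_rejected(self):
        with pytest.raises(ValueError):
            c45_fit(pd.DataFrame({"x": [], "label": []}))

    def test_pruning_never_increases_training_accuracy_or_leaves(self, default_log):
        df = build_instances(default_log, 2)
        feats = [c for c in df.columns
                 if c not in ("alert_id", "model_id", "alert_time", "label")]
        rows = df[feats].to_dict("records")

        def train_acc(tree):
            preds = [c45_predict(tree, r).class_ for r in rows]
            return np.mean(np.array(preds) == df["label"].to_numpy())

        unpruned = c45_fit(df, C45Params(min_leaf=1, prune=False))
        pruned = c45_fit(df, C45Params(min_leaf=1, prune=True))
        assert train_acc(unpruned) >= train_acc(pruned)
        assert pruned.root.n_leaves() <= unpruned.root.n_leaves()


class TestPredict:
    def test_pure_leaf_laplace_probability(self):
        df = pd.DataFrame({"x": ["a"] * 5, "label": ["responded"] * 5})
        tree = c45_fit(df, classes=("ignored", "responded"))
        pred = c45_predict(tree, {"x": "a"})
        assert pred.class_ == "responded"
        assert pred.probability == pytest.approx(6 / 7)

    def test_majority_leaf_laplace_probability(self):
        df = pd.DataFrame({"x": ["a"] * 10,
                           "label": ["responded"] * 6 + ["ignored"] * 4})
        tree = c45_fit(df)
        pred = c45_predict(tree, {"x": "a"})
        assert pred.class_ == "responded"
        assert pred.probability == pytest.approx(7 / 12)

    def test_missing_root_attribute_routes_fractionally(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0] * 3,
                           "label": (["p", "p", "q", "q"]) * 3})
        tree = c45_fit(df, C45Params(min_leaf=1, prune=False))
        assert not tree.root.is_leaf
        pred = c45_predict(tree, {"x": np.nan})
        assert sum(pred.distribution.values()) == pytest.approx(1.0)

    def test_tie_resolves_to_ignored(self):
        df = pd.DataFrame({"x": ["a"] * 4,
                           "label": ["responded"] * 2 + ["ignored"] * 2})
        tree = c45_fit(df)
        assert c45_predict(tree, {"x": "a"}).class_ == "ignored"


class TestConfusionMetrics:
    def test_hand_computed_example(self):
        out = confusion_metrics([[50, 50], [0, 100]])
        assert out["responded"]["recall"] == pytest.approx(0.5)
        assert out["responded"]["precision"] == pytest.approx(1.0)
        assert out["responded"]["f"] == pytest.approx(2 / 3)
        assert out["accuracy"] == pytest.approx(0.75)

    def test_perfect_matrix(self):
        out = confusion_metrics([[10, 0], [0, 20]])
        assert out["accuracy"] == 1.0
        for cls in ("responded", "ignored"):
            assert out[cls] == {"precision": 1.0, "recall": 1.0, "f": 1.0}

    def test_no_positive_predictions_flagged_zero(self):
        out = confusion_metrics([[0, 10], [0, 10]])
        assert out["responded"]["precision"] == 0.0
        assert out["responded"]["recall"] == 0.0
        assert any(f.startswith("undefined_precision") for f in out["flags"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([[-1, 1], [1, 1]])


def _chrono_table(n: int) -> pd.DataFrame:
    rng = np.random.default_rng(0)
    return pd.DataFrame({
        "alert_time": np.arange(n),
        "x": rng.normal(size=n),
        "label": rng.choice(["responded", "ignored"], size=n, p=[0.4, 0.6]),
    })


class TestProtocols:
    def test_study_sized_split_arithmetic(self):
        assert chrono_split_sizes(993, 0.669) == (664, 329)

    def test_chrono_split_evaluates_test_tail_only(self):
        df = _chrono_table(993)
        report = evaluate(df, majority_learner(), ChronoSplit(0.669))
        assert report.n == 329
        assert np.asarray(report.confusion).sum() == 329

    def test_majority_learner_accuracy_is_heldout_prevalence(self):
        df = _chrono_table(500)
        report = evaluate(df, majority_learner(), ChronoSplit(0.669))
        tail = df.iloc[chrono_split_sizes(500, 0.669)[0]:]
        majority = df.iloc[:chrono_split_sizes(500, 0.669)[0]]["label"].mode()[0]
        assert report.accuracy == pytest.approx((tail["label"] == majority).mean())

    def test_shuffled_input_rejected_for_chrono_split(self):
        df = _chrono_table(100).sample(frac=1.0, random_state=1)
        with pytest.raises(ValueError, match="shuffled"):
            evaluate(df, majority_learner(), ChronoSplit())

    def test_cv_folds_partition_993(self):
        y = np.array((["responded"] * 394) + (["ignored"] * 599))
        folds = cv_folds(y, 10, seed=0)
        tests = [set(te) for _, te in folds]
        assert len(tests) == 10
        union = set().union(*tests)
        assert union == set(range(993))
        assert sum(len(t) for t in tests) == 993      # disjoint + exhaustive
        assert {len(t) for t in tests} <= {99, 100}

    def test_cv10_report_covers_all_instances(self):
        df = _chrono_table(200)
        report = evaluate(df, majority_learner(), CV10(seed=1))
        assert np.asarray(report.confusion).sum() == 200

    def test_report_serializes_to_json(self, default_log):
        df = build_instances(default_log, 1)
        report = evaluate(df, majority_learner(), ChronoSplit())
        payload = report.to_json()
        assert '"protocol": "chrono_split"' in payload
        assert '"model_id": 1' in payload


class TestLogisticLearner:
    def test_recovers_separating_direction(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=400)
        p = 1 / (1 + np.exp(-(0.5 + 2.0 * x)))
        df = pd.DataFrame({"x": x,
                           "label": np.where(rng.random(400) < p, "yes", "no")})
        model = LogisticLearner().fit(df, feature_cols=["x"])
        assert model.beta[1] > 0
        hi = model.predict_proba(pd.DataFrame({"x": [2.0]}), "yes")[0]
        lo = model.predict_proba(pd.DataFrame({"x": [-2.0]}), "yes")[0]
        assert hi > 0.8 > 0.2 > lo

    def test_handles_categoricals_and_missing(self, default_log):
        df = build_instances(default_log, 3)
        model = LogisticLearner().fit(df)
        preds = model.predict(df)
        assert set(preds) <= {"responded", "ignored"}
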