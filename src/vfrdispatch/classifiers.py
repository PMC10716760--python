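"""C4.5-style decision tree, per-class evaluation metrics, and the two
evaluation protocols (stratified 10-fold CV; chronological split).

The tree is a univariate, gain-ratio tree in the C4.5 lineage:

* candidate attributes are gated to those whose information gain is at
  least the mean of the positive gains, then the admissible attribute with
  the highest gain ratio is chosen;
* numeric attributes split at the best midpoint between observed values
  (threshold chosen by information gain, the C4.5 convention);
* instances with a missing attribute value are distributed *fractionally*
  across branches in proportion to the known branch weights, both when
  scoring splits and when routing at prediction time;
* optional pessimistic-error pruning replaces a subtree by a leaf when the
  leaf's upper-confidence error estimate does not exceed the subtree's
  (no subtree raising);
* leaf probabilities are Laplace-smoothed, ``(k_c + 1) / (n + K)``, and
  aggregated over fractionally reached leaves; prediction ties resolve to
  ``"ignored"`` — for dispatch, wrongly predicting a response is the more
  costly error.

Chronological evaluation exists because one of the model configurations
uses a dynamically recomputed behavioral indicator: shuffling such rows
into CV folds would leak future behavior, so the protocol trains on the
earliest fraction of instances and tests on the remainder, and refuses
input that is not in time order.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, xlogy
from scipy.stats import beta as _beta
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "META_COLUMNS", "C45Params", "TreeNode", "C45Tree",
    "gain_ratio", "c45_fit", "c45_predict",
    "C45Learner", "LogisticLearner", "SklearnLearner",
    "random_forest_learner", "mlp_learner", "majority_learner",
    "CV10", "ChronoSplit", "EvalReport", "evaluate", "confusion_metrics",
]

#: Instance-table columns that are metadata, never features.
META_COLUMNS = ("alert_id", "model_id", "alert_time")
LABEL = "label"
_EPS = 1e-12
_MIN_WEIGHT = 1e-6          # fractional instances lighter than this are dropped


# ---------------------------------------------------------------------------
# dataset plumbing

def _feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in META_COLUMNS and c != LABEL]


def _is_numeric(series: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(series)


class _Data:
    """Columnar view of an instance table for tree induction."""

    def __init__(self, df: pd.DataFrame, feature_cols: Sequence[str],
                 label_col: str = LABEL, classes: Sequence[str] | None = None):
        y_raw = df[label_col].astype(str).to_numpy()
        self.classes = tuple(classes) if classes is not None else tuple(sorted(set(y_raw)))
        lookup = {c: i for i, c in enumerate(self.classes)}
        self.y = np.array([lookup[v] for v in y_raw], dtype=np.intp)
        self.kinds: dict[str, str] = {}
        self.columns: dict[str, np.ndarray] = {}
        self.known: dict[str, np.ndarray] = {}
        for c in feature_cols:
            s = df[c]
            if _is_numeric(s):
                vals = s.to_numpy(dtype=float)
                self.kinds[c] = "numeric"
                self.columns[c] = vals
                self.known[c] = ~np.isnan(vals)
            else:
                raw = s.to_numpy(dtype=object)
                known = np.array([not (v is None or (isinstance(v, float) and np.isnan(v)))
                                  for v in raw])
                self.kinds[c] = "categorical"
                self.columns[c] = np.array([str(v) if k else "" for v, k in zip(raw, known)],
                                           dtype=object)
                self.known[c] = known
        self.n = len(df)

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def _entropy(counts: np.ndarray) -> np.ndarray:
    """Shannon entropy in bits along the last axis of weighted class counts."""
    tot = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tot > 0, counts / np.where(tot > 0, tot, 1.0), 0.0)
    return -(xlogy(p, p).sum(axis=-1)) / np.log(2.0)


def _class_counts(y: np.ndarray, w: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(y, weights=w, minlength=n_classes)


# ---------------------------------------------------------------------------
# split scoring

@dataclass(frozen=True)
class _SplitScore:
    info_gain: float
    split_info: float
    gain_ratio: float
    threshold: float | None          # numeric splits only
    branch_keys: tuple               # categorical values or ("le", "gt")
    branch_weights: tuple[float, ...]
    admissible: bool


def _score_branches(branch_counts: np.ndarray, total_counts: np.ndarray,
                    missing_counts: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Info gain and split info given known per-branch class counts.

    Missing-value mass is spread over branches in proportion to the known
    branch weights before entropies are taken.
    """
    W = float(total_counts.sum())
    WK = float(branch_counts.sum())
    Wm = float(missing_counts.sum())
    if WK <= _EPS or W <= _EPS:
        return 0.0, 0.0, branch_counts
    frac = branch_counts.sum(axis=-1) / WK                    # (B,)
    full = branch_counts + frac[:, None] * missing_counts      # (B, K)
    weights = full.sum(axis=-1) / W
    cond = float((weights * _entropy(full)).sum())
    info_gain = float(_entropy(total_counts[None, :])[0] - cond)
    nz = weights[weights > _EPS]
    split_info = float(-(nz * np.log2(nz)).sum())
    return info_gain, split_info, full


def _score_categorical(data: _Data, attr: str, idx: np.ndarray, w: np.ndarray,
                       min_leaf: float) -> _SplitScore | None:
    known = data.known[attr][idx]
    if not known.any():
        return None
    vals = data.columns[attr][idx]
    y, K = data.y[idx], data.n_classes
    total = _class_counts(y, w, K)
    missing = _class_counts(y[~known], w[~known], K)
    keys = sorted(set(vals[known]))
    if len(keys) < 2:
        return None
    branch = np.zeros((len(keys), K))
    for b, key in enumerate(keys):
        sel = known & (vals == key)
        branch[b] = _class_counts(y[sel], w[sel], K)
    ig, si, full = _score_branches(branch, total, missing)
    bw = tuple(full.sum(axis=-1))
    admissible = sum(x >= min_leaf for x in bw) >= 2
    gr = ig / si if si > _EPS else 0.0
    return _SplitScore(ig, si, gr, None, tuple(keys), bw, admissible)


def _score_numeric(data: _Data, attr: str, idx: np.ndarray, w: np.ndarray,
                   min_leaf: float) -> _SplitScore | None:
    known = data.known[attr][idx]
    if known.sum() < 2:
        return None
    v = data.columns[attr][idx][known]
    y, K = data.y[idx], data.n_classes
    yk, wk = y[known], w[known]
    total = _class_counts(y, w, K)
    missing = _class_counts(y[~known], w[~known], K)
    W, Wm = float(total.sum()), float(missing.sum())

    order = np.argsort(v, kind="stable")
    v, yk, wk = v[order], yk[order], wk[order]
    cut = np.nonzero(np.diff(v) > 0)[0]           # split after position i
    if cut.size == 0:
        return None
    onehot = np.zeros((len(yk), K))
    onehot[np.arange(len(yk)), yk] = wk
    cum = np.cumsum(onehot, axis=0)
    Kc = cum[-1]
    L = cum[cut]                                   # (T, K) known left counts
    R = Kc[None, :] - L
    WK = float(Kc.sum())
    fl = L.sum(axis=-1) / WK
    fullL = L + fl[:, None] * missing[None, :]
    fullR = R + (1 - fl)[:, None] * missing[None, :]
    WbL, WbR = fullL.sum(axis=-1), fullR.sum(axis=-1)
    cond = (WbL * _entropy(fullL) + WbR * _entropy(fullR)) / W
    ig = _entropy(total[None, :])[0] - cond

    ok = (WbL >= min_leaf) & (WbR >= min_leaf)
    pick_from = np.nonzero(ok)[0] if ok.any() else np.arange(len(cut))
    best = pick_from[int(np.argmax(ig[pick_from]))]
    thr = float((v[cut[best]] + v[cut[best] + 1]) / 2.0)
    pL, pR = WbL[best] / W, WbR[best] / W
    si = float(-sum(p * np.log2(p) for p in (pL, pR) if p > _EPS))
    igb = float(ig[best])
    gr = igb / si if si > _EPS else 0.0
    admissible = bool(ok[best])
    return _SplitScore(igb, si, gr, thr, ("le", "gt"),
                       (float(WbL[best]), float(WbR[best])), admissible)


def gain_ratio(instances: pd.DataFrame, attribute: str,
               label_col: str = LABEL,
               weights: np.ndarray | None = None) -> dict:
    """Score one attribute: information gain, split information, gain ratio.

    ``info_gain = H(label) − Σ_b w_b·H(label | branch)`` with instances
    missing the attribute distributed fractionally by branch weight;
    ``split_info`` is the entropy of the branch weights; ``gain_ratio`` is
    their quotient (0 when split information is 0).  For numeric
    attributes every midpoint between observed sorted values is evaluated
    and the best is returned as ``best_threshold``.
    """
    feats = _feature_columns(instances)
    if attribute not in feats:
        raise KeyError(f"unknown attribute {attribute!r}")
    data = _Data(instances, feats, label_col=label_col)
    idx = np.arange(data.n)
    w = np.ones(data.n) if weights is None else np.asarray(weights, dtype=float)
    zero = {"info_gain": 0.0, "split_info": 0.0, "gain_ratio": 0.0}
    if data.n < 2 or len(set(data.y.tolist())) < 2:
        return dict(zero, **({"best_threshold": None}
                             if data.kinds[attribute] == "numeric" else {}))
    if data.kinds[attribute] == "numeric":
        s = _score_numeric(data, attribute, idx, w, min_leaf=0.0)
        if s is None:
            return dict(zero, best_threshold=None)
        return {"info_gain": s.info_gain, "split_info": s.split_info,
                "gain_ratio": s.gain_ratio, "best_threshold": s.threshold}
    s = _score_categorical(data, attribute, idx, w, min_leaf=0.0)
    if s is None:
        return zero
    return {"info_gain": s.info_gain, "split_info": s.split_info,
            "gain_ratio": s.gain_ratio}


# ---------------------------------------------------------------------------
# tree induction

@dataclass
class C45Params:
    min_leaf: float = 2.0
    prune: bool = True
    confidence: float = 0.25


@dataclass
class TreeNode:
    class_counts: np.ndarray
    attribute: str | None = None
    kind: str | None = None                      # "numeric" | "categorical"
    threshold: float | None = None
    branches: list[tuple[object, float, "TreeNode"]] = field(default_factory=list)
    # each branch: (key, fraction of known weight, child)

    @property
    def is_leaf(self) -> bool:
        return self.attribute is None

    def n_leaves(self) -> int:
        return 1 if self.is_leaf else sum(c.n_leaves() for _, _, c in self.branches)

    def depth(self) -> int:
        return 0 if self.is_leaf else 1 + max(c.depth() for _, _, c in self.branches)


@dataclass
class C45Tree:
    root: TreeNode
    classes: tuple[str, ...]
    kinds: dict[str, str]
    params: C45Params


def _choose_split(data: _Data, idx: np.ndarray, w: np.ndarray,
                  params: C45Params) -> tuple[str, _SplitScore] | None:
    """C4.5 attribute selection.

    Among structurally admissible splits (at least two branches of
    ``min_leaf`` weight), gate to those with information gain at least the
    mean of the positive gains, then take the highest gain ratio.  When no
    split has positive gain, any admissible split is eligible — a
    zero-gain split can still be useful (the classic XOR configuration)
    and is later removed by pruning if it was not.
    """
    scores: list[tuple[str, _SplitScore]] = []
    for attr in data.kinds:
        fn = _score_numeric if data.kinds[attr] == "numeric" else _score_categorical
        s = fn(data, attr, idx, w, params.min_leaf)
        if s is not None and s.admissible:
            scores.append((attr, s))
    if not scores:
        return None
    positive = [s.info_gain for _, s in scores if s.info_gain > _EPS]
    if positive:
        avg = float(np.mean(positive))
        eligible = [(a, s) for a, s in scores if s.info_gain >= avg - 1e-9]
    else:
        eligible = scores
    return max(eligible, key=lambda t: t[1].gain_ratio)


def _partition(data: _Data, attr: str, score: _SplitScore,
               idx: np.ndarray, w: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    known = data.known[attr][idx]
    vals = data.columns[attr][idx]
    WK = float(w[known].sum())
    out = []
    for b, key in enumerate(score.branch_keys):
        if data.kinds[attr] == "numeric":
            sel = known & ((vals <= score.threshold) if key == "le" else (vals > score.threshold))
        else:
            sel = known & (vals == key)
        frac = float(w[known & sel].sum()) / WK if WK > 0 else 0.0
        bi = np.concatenate([idx[sel], idx[~known]])
        bw = np.concatenate([w[sel], w[~known] * frac])
        keep = bw >= _MIN_WEIGHT
        out.append((bi[keep], bw[keep]))
    return out


def _grow(data: _Data, idx: np.ndarray, w: np.ndarray, params: C45Params) -> TreeNode:
    counts = _class_counts(data.y[idx], w, data.n_classes)
    node = TreeNode(class_counts=counts)
    if (float(_entropy(counts[None, :])[0]) <= _EPS
            or float(counts.sum()) < 2 * params.min_leaf):
        return node
    chosen = _choose_split(data, idx, w, params)
    if chosen is None:
        return node
    attr, score = chosen
    parts = _partition(data, attr, score, idx, w)
    WK = sum(score.branch_weights)
    node.attribute, node.kind, node.threshold = attr, data.kinds[attr], score.threshold
    node.branches = [
        (key, bw / WK if WK > 0 else 0.0, _grow(data, bi, bwts, params))
        for key, bw, (bi, bwts) in zip(score.branch_keys, score.branch_weights, parts)
    ]
    return node


def _upper_error_rate(errors: float, n: float, confidence: float) -> float:
    """Upper confidence limit on a binomial error rate (Clopper-Pearson).

    Reduces to the C4.5 special case ``1 − cf^(1/N)`` for zero errors.
    """
    if n <= 0:
        return 0.0
    if errors >= n:
        return 1.0
    return float(_beta.ppf(1.0 - confidence, errors + 1.0, n - errors))


def _subtree_estimate(node: TreeNode, confidence: float) -> float:
    W = float(node.class_counts.sum())
    E = W - float(node.class_counts.max())
    if node.is_leaf:
        return W * _upper_error_rate(E, W, confidence)
    return sum(_subtree_estimate(c, confidence) for _, _, c in node.branches)


def _prune(node: TreeNode, confidence: float) -> TreeNode:
    if node.is_leaf:
        return node
    node.branches = [(k, f, _prune(c, confidence)) for k, f, c in node.branches]
    W = float(node.class_counts.sum())
    E = W - float(node.class_counts.max())
    leaf_est = W * _upper_error_rate(E, W, confidence)
    if leaf_est <= _subtree_estimate(node, confidence) + 1e-9:
        return TreeNode(class_counts=node.class_counts)
    return node


def c45_fit(instances: pd.DataFrame, params: C45Params | None = None,
            feature_cols: Sequence[str] | None = None,
            label_col: str = LABEL,
            classes: Sequence[str] | None = None) -> C45Tree:
    """Fit a gain-ratio decision tree; deterministic given the row order.

    ``classes`` fixes the class space (so Laplace smoothing is over the
    task's classes even when a training sample happens to miss one);
    by default the observed labels, sorted.
    """
    if len(instances) == 0:
        raise ValueError("cannot fit a tree on an empty instance set")
    params = params or C45Params()
    feats = list(feature_cols) if feature_cols is not None else _feature_columns(instances)
    data = _Data(instances, feats, label_col=label_col, classes=classes)
    root = _grow(data, np.arange(data.n), np.ones(data.n), params)
    if params.prune:
        root = _prune(root, params.confidence)
    return C45Tree(root=root, classes=data.classes, kinds=dict(data.kinds), params=params)


# ---------------------------------------------------------------------------
# prediction

@dataclass(frozen=True)
class Prediction:
    class_: str
    probability: float                       # of the predicted class
    distribution: dict[str, float]           # Laplace-smoothed, sums to 1


def _is_missing(value: object) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value))


def _route(node: TreeNode, instance: Mapping, weight: float,
           acc: np.ndarray, n_classes: int) -> None:
    if node.is_leaf:
        n = float(node.class_counts.sum())
        acc += weight * (node.class_counts + 1.0) / (n + n_classes)
        return
    value = instance.get(node.attribute)
    if node.kind == "numeric" and not _is_missing(value):
        key = "le" if float(value) <= node.threshold else "gt"
        for k, _, child in node.branches:
            if k == key:
                _route(child, instance, weight, acc, n_classes)
                return
        value = None                          # threshold branch vanished: treat as missing
    elif node.kind == "categorical" and not _is_missing(value):
        for k, _, child in node.branches:
            if k == str(value):
                _route(child, instance, weight, acc, n_classes)
                return
        value = None                          # unseen category: fractional routing
    total_f = sum(f for _, f, _ in node.branches)
    for _, f, child in node.branches:
        if total_f > 0 and f > 0:
            _route(child, instance, weight * f / total_f, acc, n_classes)


def c45_predict(tree: C45Tree, instance: Mapping) -> Prediction:
    """Route one instance to its (possibly fractional) leaves.

    The class distribution is the weighted sum of Laplace-smoothed leaf
    frequencies ``(k_c + 1)/(n + K)``; the predicted class is the argmax,
    with ties resolved to ``"ignored"`` when present (the safer dispatch
    assumption), else to the first class.
    """
    K = len(tree.classes)
    acc = np.zeros(K)
    _route(tree.root, instance, 1.0, acc, K)
    dist = {c: float(acc[i]) for i, c in enumerate(tree.classes)}
    best = max(dist.values())
    winners = [c for c, p in dist.items() if abs(p - best) <= 1e-12]
    cls = "ignored" if len(winners) > 1 and "ignored" in winners else winners[0]
    return Prediction(class_=cls, probability=dist[cls], distribution=dist)


# ---------------------------------------------------------------------------
# learners (uniform fit/predict adapters)

class C45Model:
    def __init__(self, tree: C45Tree, feature_cols: list[str]):
        self.tree, self.feature_cols = tree, feature_cols

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return np.array([c45_predict(self.tree, row).class_
                         for row in df[self.feature_cols].to_dict("records")])

    def predict_proba(self, df: pd.DataFrame, class_: str) -> np.ndarray:
        return np.array([c45_predict(self.tree, row).distribution[class_]
                         for row in df[self.feature_cols].to_dict("records")])


class C45Learner:
    """The package's native tree learner (default hyperparameters as in Weka's J48)."""

    def __init__(self, params: C45Params | None = None):
        self.params = params or C45Params()

    def fit(self, df: pd.DataFrame, feature_cols: Sequence[str] | None = None) -> C45Model:
        feats = list(feature_cols) if feature_cols is not None else _feature_columns(df)
        return C45Model(c45_fit(df, self.params, feature_cols=feats), feats)


class _Encoder:
    """One-hot + mean-impute encoding shared by the non-tree learners."""

    def fit(self, df: pd.DataFrame, feature_cols: Sequence[str]) -> None:
        self.feature_cols = list(feature_cols)
        self.numeric = [c for c in feature_cols if _is_numeric(df[c])]
        self.categorical = [c for c in feature_cols if c not in self.numeric]
        self.means = {c: float(np.nanmean(df[c].to_numpy(dtype=float)))
                      if np.isfinite(np.nanmean(df[c].to_numpy(dtype=float))) else 0.0
                      for c in self.numeric}
        self.levels = {c: sorted(map(str, df[c].dropna().unique())) for c in self.categorical}

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(df))]
        for c in self.numeric:
            v = df[c].to_numpy(dtype=float)
            cols.append(np.where(np.isnan(v), self.means[c], v))
        for c in self.categorical:
            v = df[c].astype(str).to_numpy()
            for level in self.levels[c][1:]:
                cols.append((v == level).astype(float))
        return np.column_stack(cols)


class LogisticModel:
    def __init__(self, enc: _Encoder, beta: np.ndarray, classes: tuple[str, str]):
        self.enc, self.beta, self.classes = enc, beta, classes

    def predict_proba(self, df: pd.DataFrame, class_: str | None = None) -> np.ndarray:
        p1 = expit(self.enc.transform(df) @ self.beta)    # P(classes[1])
        if class_ is None or class_ == self.classes[1]:
            return p1
        return 1.0 - p1

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        p1 = self.predict_proba(df)
        return np.where(p1 > 0.5, self.classes[1], self.classes[0])


class LogisticLearner:
    """Binary logistic regression fit by Newton-Raphson.

    Tolerance 1e-8 on the step, at most 100 iterations, tiny ridge term
    for numerical stability.  Categorical features are one-hot encoded,
    missing numerics mean-imputed.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100, ridge: float = 1e-8):
        self.tol, self.max_iter, self.ridge = tol, max_iter, ridge

    def fit(self, df: pd.DataFrame, feature_cols: Sequence[str] | None = None) -> LogisticModel:
        feats = list(feature_cols) if feature_cols is not None else _feature_columns(df)
        classes = tuple(sorted(df[LABEL].astype(str).unique()))
        if len(classes) == 1:
            classes = (classes[0], classes[0])
        if len(classes) > 2:
            raise ValueError("LogisticLearner handles binary labels only")
        enc = _Encoder()
        enc.fit(df, feats)
        X = enc.transform(df)
        y = (df[LABEL].astype(str).to_numpy() == classes[1]).astype(float)
        beta = np.zeros(X.shape[1])
        for _ in range(self.max_iter):
            p = expit(X @ beta)
            Wd = np.clip(p * (1 - p), 1e-10, None)
            H = (X * Wd[:, None]).T @ X + self.ridge * np.eye(X.shape[1])
            step = np.linalg.solve(H, X.T @ (y - p))
            beta += step
            if np.max(np.abs(step)) < self.tol:
                break
        return LogisticModel(enc, beta, classes)  # type: ignore[arg-type]


class _SklearnModel:
    def __init__(self, enc: _Encoder, est, classes: np.ndarray):
        self.enc, self.est, self.classes = enc, est, classes

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return self.est.predict(self.enc.transform(df))


class SklearnLearner:
    """Adapter exposing any scikit-learn classifier through fit/predict.

    Used for the pluggable reference learners (random forest, multilayer
    perceptron) that complement the native tree.
    """

    def __init__(self, estimator_factory: Callable):
        self.estimator_factory = estimator_factory

    def fit(self, df: pd.DataFrame, feature_cols: Sequence[str] | None = None) -> _SklearnModel:
        feats = list(feature_cols) if feature_cols is not None else _feature_columns(df)
        enc = _Encoder()
        enc.fit(df, feats)
        est = self.estimator_factory()
        est.fit(enc.transform(df), df[LABEL].astype(str).to_numpy())
        return _SklearnModel(enc, est, getattr(est, "classes_", None))


def random_forest_learner(seed: int = 0, **kwargs) -> SklearnLearner:
    from sklearn.ensemble import RandomForestClassifier
    return SklearnLearner(lambda: RandomForestClassifier(random_state=seed, **kwargs))


def mlp_learner(seed: int = 0, **kwargs) -> SklearnLearner:
    from sklearn.neural_network import MLPClassifier
    kwargs.setdefault("max_iter", 500)
    return SklearnLearner(lambda: MLPClassifier(random_state=seed, **kwargs))


class _MajorityModel:
    def __init__(self, cls: str):
        self.cls = cls

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return np.full(len(df), self.cls, dtype=object)


class majority_learner:
    """Dummy learner predicting the training majority class (a baseline)."""

    def fit(self, df: pd.DataFrame, feature_cols=None) -> _MajorityModel:
        return _MajorityModel(df[LABEL].astype(str).mode().iloc[0])


# ---------------------------------------------------------------------------
# evaluation

@dataclass(frozen=True)
class CV10:
    """Stratified 10-fold cross-validation (disjoint, exhaustive, sizes ±1)."""

    seed: int = 0
    folds: int = 10

    name = "cv10"


@dataclass(frozen=True)
class ChronoSplit:
    """Order-preserving chronological split: earliest fraction trains."""

    train_frac: float = 0.669

    name = "chrono_split"


@dataclass
class EvalReport:
    protocol: str
    accuracy: float
    per_class: dict[str, dict[str, float]]
    confusion: list[list[int]]                # [[tp, fn], [fp, tn]] wrt positive class
    positive_class: str
    n: int
    flags: list[str] = field(default_factory=list)
    model_id: int | None = None

    def to_json(self) -> str:
        return json.dumps({
            "model_id": self.model_id, "protocol": self.protocol,
            "accuracy": self.accuracy, "per_class": self.per_class,
            "confusion": self.confusion, "positive_class": self.positive_class,
            "n": self.n, "flags": self.flags,
        }, indent=2)


def confusion_metrics(confusion: Sequence[Sequence[int]],
                      classes: Sequence[str] = ("responded", "ignored")) -> dict:
    """Per-class precision/recall/F and accuracy from a 2×2 matrix.

    The matrix is ``[[tp, fn], [fp, tn]]`` with ``classes[0]`` positive.
    Ratios with a zero denominator are reported as 0 and flagged.
    """
    m = np.asarray(confusion, dtype=float)
    if m.shape != (2, 2):
        raise ValueError("confusion matrix must be 2x2")
    if (m < 0).any():
        raise ValueError("confusion counts must be non-negative")
    (tp, fn), (fp, tn) = m
    flags: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(f"undefined_{name}")
            return 0.0
        return num / den

    out: dict[str, object] = {"accuracy": ratio(tp + tn, m.sum(), "accuracy"),
                              "flags": flags}
    for cls, (t, miss, false_pos) in ((classes[0], (tp, fn, fp)),
                                      (classes[1], (tn, fp, fn))):
        precision = ratio(t, t + false_pos, f"precision_{cls}")
        recall = ratio(t, t + miss, f"recall_{cls}")
        f = ratio(2 * precision * recall, precision + recall, f"f_{cls}")
        out[cls] = {"precision": precision, "recall": recall, "f": f}
    return out


def _confusion_from(y_true: np.ndarray, y_pred: np.ndarray,
                    positive: str, negative: str) -> np.ndarray:
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    return np.array([[tp, fn], [fp, tn]])


def evaluate(instances: pd.DataFrame, learner,
             protocol: CV10 | ChronoSplit) -> EvalReport:
    """Run one evaluation protocol and aggregate held-out predictions.

    CV10 builds stratified, disjoint, exhaustive folds (sizes within one
    of each other).  ChronoSplit trains on the first
    ``floor(train_frac·n)`` rows and tests on the rest; it requires an
    ``alert_time`` column in non-decreasing order and raises otherwise —
    behavioral features make temporal order part of the data contract.
    """
    df = instances.reset_index(drop=True)
    y = df[LABEL].astype(str).to_numpy()
    classes = sorted(set(y))
    positive = "responded" if "responded" in classes else classes[0]
    negative = "ignored" if "ignored" in classes else \
        next(c for c in classes if c != positive)

    if isinstance(protocol, CV10):
        if len(df) < protocol.folds:
            raise ValueError(f"need at least {protocol.folds} instances for CV")
        y_pred = np.empty(len(df), dtype=object)
        for train_idx, test_idx in cv_folds(y, protocol.folds, protocol.seed):
            model = learner.fit(df.iloc[train_idx])
            y_pred[test_idx] = model.predict(df.iloc[test_idx])
        y_eval, pred_eval, n = y, y_pred.astype(str), len(df)
    else:
        if "alert_time" not in df.columns:
            raise ValueError("chronological split requires an alert_time column")
        times = df["alert_time"].to_numpy()
        if np.any(np.diff(times) < 0):
            raise ValueError("chronological split requires time-ordered instances; "
                             "input appears shuffled")
        n_train = int(np.floor(protocol.train_frac * len(df)))
        if n_train == 0 or n_train == len(df):
            raise ValueError("degenerate chronological split")
        model = learner.fit(df.iloc[:n_train])
        y_eval = y[n_train:]
        pred_eval = np.asarray(model.predict(df.iloc[n_train:]), dtype=str)
        n = len(df) - n_train

    conf = _confusion_from(y_eval, pred_eval, positive, negative)
    metrics = confusion_metrics(conf, classes=(positive, negative))
    model_id = int(df["model_id"].iloc[0]) if "model_id" in df.columns and len(df) else None
    return EvalReport(
        protocol=protocol.name,
        accuracy=metrics["accuracy"],
        per_class={positive: metrics[positive], negative: metrics[negative]},
        confusion=conf.tolist(), positive_class=positive, n=n,
        flags=metrics["flags"], model_id=model_id)


def cv_folds(y: Sequence[str], folds: int = 10,
             seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold index pairs (train, test): disjoint, exhaustive, sizes ±1."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), np.asarray(y)))


def chrono_split_sizes(n: int, train_frac: float = 0.669) -> tuple[int, int]:
    """Train/test sizes of the chronological split (e.g. 993 → 664/329)."""
    n_train = int(np.floor(train_frac * n))
    return n_train, n - n_train
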