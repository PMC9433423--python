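"""Bagged decision trees with surrogate splits for missing data.

500 bootstrap-resampled CART trees (Gini impurity, exhaustive split
search, minimum leaf size 3, all predictors eligible at every split —
unlike a random forest) classify events as noxious or nonnoxious.  Each
internal node carries up to five surrogate splits, ranked by agreement
with the primary split on the in-node bootstrap rows; at prediction
time a row missing the primary split variable is routed by the best
available surrogate, and failing that by the branch that received the
training majority.  Per-tree in-bag/out-of-bag masks are retained for
the out-of-bag permutation importance.

The per-node split search is delegated to scikit-learn's CART; the
surrogate bookkeeping, missing-value routing, and bagging/OOB logic
live here.  Surrogates are computed lazily per node and cached, since
most predictions never encounter a missing primary variable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

#: label encoding: ties in the ensemble vote break toward nonnoxious
NEGATIVE, POSITIVE = "nonnoxious", "noxious"


@dataclass
class SurrogateSplit:
    feature: int
    threshold: float
    left_if_leq: bool
    agreement: float


@dataclass
class BaggedTreeModel:
    trees: list
    inbag_indices: list
    feature_names: list
    X_train: np.ndarray  # float matrix with NaN for missing
    y_train: np.ndarray  # 0 = nonnoxious, 1 = noxious
    n_surrogates: int = 5
    seed: int = 0
    _surrogate_cache: dict = field(default_factory=dict, repr=False)
    _paths_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def oob_mask(self, t: int) -> np.ndarray:
        mask = np.ones(self.X_train.shape[0], dtype=bool)
        mask[self.inbag_indices[t]] = False
        return mask


def encode_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "iub":
        return arr.astype(int)
    return (arr == POSITIVE).astype(int)


def train_bagged_trees(X, y, feature_names=None, n_trees: int = 500,
                       min_leaf: int = 3, n_surrogates: int = 5,
                       seed: int = 0, infant_ids=None,
                       bootstrap_by_infant: bool = False) -> BaggedTreeModel:
    """Fit the bagged-tree ensemble.

    ``X`` is (n_rows, n_features) with NaN marking missing entries; a
    predictor that is missing everywhere is excluded from splitting with
    a warning.  Bootstrap resampling is at the observation level by
    default; ``bootstrap_by_infant`` resamples infants (keeping their
    paired rows together) instead.
    """
    X = np.asarray(X, dtype=float)
    y = encode_labels(y)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    feature_names = list(feature_names)
    for cls in (0, 1):
        if np.sum(y == cls) < 2:
            raise ValueError("need at least 2 observations per class")
    all_missing = np.flatnonzero(np.all(np.isnan(X), axis=0))
    X_fit = X.copy()
    if all_missing.size:
        warnings.warn(
            "predictors entirely missing in training excluded from splits: "
            + ", ".join(feature_names[j] for j in all_missing))
        # a constant column is never a valid split, which excludes it
        X_fit[:, all_missing] = 0.0
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    trees, inbag = [], []
    if bootstrap_by_infant:
        ids = np.asarray(infant_ids)
        uniq = np.unique(ids)
        groups = {u: np.flatnonzero(ids == u) for u in uniq}
    for t in range(n_trees):
        if bootstrap_by_infant:
            pick = rng.choice(uniq, size=uniq.size, replace=True)
            idx = np.concatenate([groups[u] for u in pick])
        else:
            idx = rng.integers(0, n, n)
        clf = DecisionTreeClassifier(
            criterion="gini", min_samples_leaf=min_leaf, max_features=None,
            random_state=int(rng.integers(0, 2**31 - 1)))
        clf.fit(X_fit[idx], y[idx])
        trees.append(clf)
        inbag.append(idx)
    return BaggedTreeModel(trees=trees, inbag_indices=inbag,
                           feature_names=feature_names, X_train=X_fit,
                           y_train=y, n_surrogates=n_surrogates, seed=seed)


def _node_rows(model: BaggedTreeModel, t: int) -> dict:
    """Map node id -> bootstrap row indices reaching it (cached per tree)."""
    if t not in model._paths_cache:
        idx = model.inbag_indices[t]
        paths = model.trees[t].decision_path(model.X_train[idx]).tocsc()
        model._paths_cache[t] = {
            node: idx[paths.indices[paths.indptr[node]:paths.indptr[node + 1]]]
            for node in range(paths.shape[1])}
    return model._paths_cache[t]


def _surrogates(model: BaggedTreeModel, t: int, node: int) -> list:
    key = (t, node)
    if key in model._surrogate_cache:
        return model._surrogate_cache[key]
    tree = model.trees[t].tree_
    f, thr = tree.feature[node], tree.threshold[node]
    rows = _node_rows(model, t).get(node, np.empty(0, dtype=int))
    X = model.X_train
    prim = X[rows, f]
    ok = ~np.isnan(prim)
    rows, prim = rows[ok], prim[ok]
    out: list[SurrogateSplit] = []
    if rows.size >= 2:
        left = prim <= thr
        n_left = int(left.sum())
        majority = max(n_left, rows.size - n_left) / rows.size
        for g in range(X.shape[1]):
            if g == f:
                continue
            xg = X[rows, g]
            valid = ~np.isnan(xg)
            if valid.sum() < 2:
                continue
            xv, lv = xg[valid], left[valid]
            order = np.argsort(xv, kind="stable")
            xv, lv = xv[order], lv[order]
            # candidate thresholds between distinct consecutive values
            distinct = np.flatnonzero(np.diff(xv) > 0)
            if distinct.size == 0:
                continue
            cum_left = np.cumsum(lv)
            total_left = cum_left[-1]
            nv = xv.size
            # rows 0..i go left under the surrogate "x <= midpoint(i)"
            m_leq_left = cum_left[distinct] + (
                (nv - (distinct + 1)) - (total_left - cum_left[distinct]))
            m_leq_right = nv - m_leq_left
            best_i = int(np.argmax(np.maximum(m_leq_left, m_leq_right)))
            m1, m2 = m_leq_left[best_i], m_leq_right[best_i]
            agree = max(m1, m2) / nv
            if agree > majority + 1e-12:
                cut = 0.5 * (xv[distinct[best_i]] + xv[distinct[best_i] + 1])
                out.append(SurrogateSplit(g, float(cut), bool(m1 >= m2),
                                          float(agree)))
        out.sort(key=lambda s: -s.agreement)
        out = out[:model.n_surrogates]
    model._surrogate_cache[key] = out
    return out


def _predict_row(model: BaggedTreeModel, t: int, x: np.ndarray) -> int:
    tree = model.trees[t].tree_
    node = 0
    while tree.children_left[node] != -1:
        f = tree.feature[node]
        v = x[f]
        go_left = None
        if not np.isnan(v):
            go_left = v <= tree.threshold[node]
        else:
            for s in _surrogates(model, t, node):
                sv = x[s.feature]
                if not np.isnan(sv):
                    go_left = (sv <= s.threshold) == s.left_if_leq
                    break
            if go_left is None:  # training-majority fallback
                left, right = tree.children_left[node], tree.children_right[node]
                go_left = (tree.weighted_n_node_samples[left]
                           >= tree.weighted_n_node_samples[right])
        node = tree.children_left[node] if go_left else tree.children_right[node]
    counts = tree.value[node][0]
    classes = model.trees[t].classes_
    return int(classes[np.argmax(counts)])


def predict_tree(model: BaggedTreeModel, t: int, X: np.ndarray) -> np.ndarray:
    """Per-tree class prediction; complete rows use the fast C path,
    rows with missing entries are routed through the surrogates."""
    X = np.asarray(X, dtype=float)
    pred = np.empty(X.shape[0], dtype=int)
    has_nan = np.isnan(X).any(axis=1)
    if (~has_nan).any():
        pred[~has_nan] = model.trees[t].predict(X[~has_nan]).astype(int)
    for i in np.flatnonzero(has_nan):
        pred[i] = _predict_row(model, t, X[i])
    return pred


def predict(model: BaggedTreeModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble prediction: majority vote over trees and the fraction of
    trees voting noxious (a probability-like score in [0, 1]).  Vote
    ties break toward nonnoxious."""
    X = np.asarray(X, dtype=float)
    votes = np.zeros(X.shape[0])
    for t in range(model.n_trees):
        votes += predict_tree(model, t, X)
    frac = votes / model.n_trees
    labels = np.where(frac > 0.5, POSITIVE, NEGATIVE)
    return labels, frac
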