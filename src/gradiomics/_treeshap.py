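"""Path-dependent tree-Shapley values for decision-tree ensembles.

Implements the polynomial-time TreeSHAP recursion (EXTEND/UNWIND over the
unique features of each root-leaf path, with per-node training covers
supplying the conditional expectations) plus an exponential-time
brute-force subset-enumeration oracle used to validate it on small trees.

Trees are converted into a flat array form from either scikit-learn
random forests or XGBoost boosters; forest outputs are lesion-class
probabilities (mean over trees), boosted outputs are log-odds margins
(sum over trees plus the base margin).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import factorial

import numpy as np

from .errors import ConfigurationError

__all__ = ["TreeArrays", "trees_from_model", "tree_shap_values", "brute_force_shapley"]


@dataclass(frozen=True)
class TreeArrays:
    """One decision tree in flat array form.

    ``lte=True`` means a sample goes left when ``x[feature] <= threshold``
    (scikit-learn convention); ``lte=False`` means left on strict ``<``
    (XGBoost convention). ``value`` holds the (already scaled) leaf
    outputs; ``cover`` the training weight that reached each node.
    """

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray
    cover: np.ndarray
    lte: bool = True

    def is_leaf(self, node: int) -> bool:
        return self.children_left[node] < 0

    def goes_left(self, node: int, x: np.ndarray) -> bool:
        v = x[self.feature[node]]
        t = self.threshold[node]
        if self.lte:
            return bool(v <= t)
        # XGBoost evaluates splits in float32; replicate to route identically
        return bool(np.float32(v) < np.float32(t))

    def predict_one(self, x: np.ndarray) -> float:
        node = 0
        while not self.is_leaf(node):
            node = self.children_left[node] if self.goes_left(node, x) else self.children_right[node]
        return float(self.value[node])

    def expectation(self, node: int = 0) -> float:
        """Cover-weighted mean leaf value below ``node``."""
        if self.is_leaf(node):
            return float(self.value[node])
        l, r = self.children_left[node], self.children_right[node]
        wl, wr = self.cover[l], self.cover[r]
        return (wl * self.expectation(l) + wr * self.expectation(r)) / (wl + wr)


# ---------------------------------------------------------------------------
# model conversion
# ---------------------------------------------------------------------------


def trees_from_model(model) -> tuple[list[TreeArrays], float, str]:
    """(trees, base_offset, output_kind) for a supported tree ensemble.

    output_kind is "probability" (random forest: mean of per-tree lesion
    probabilities) or "margin" (XGBoost: sum of leaf values + base margin).
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.tree import DecisionTreeClassifier
    from xgboost import XGBClassifier

    if isinstance(model, RandomForestClassifier):
        trees = [_from_sklearn_tree(e.tree_, scale=1.0 / len(model.estimators_)) for e in model.estimators_]
        return trees, 0.0, "probability"
    if isinstance(model, DecisionTreeClassifier):
        return [_from_sklearn_tree(model.tree_, scale=1.0)], 0.0, "probability"
    if isinstance(model, XGBClassifier):
        booster = model.get_booster()
        cfg = json.loads(booster.save_config())
        base_score = float(cfg["learner"]["learner_model_param"]["base_score"])
        base_margin = float(np.log(base_score / (1.0 - base_score)))
        return _from_xgb_booster(booster), base_margin, "margin"
    raise ConfigurationError(
        f"unsupported model type {type(model).__name__}: tree-Shapley needs a "
        "random forest or XGBoost classifier"
    )


def _from_sklearn_tree(t, scale: float) -> TreeArrays:
    counts = t.value[:, 0, :]  # (nodes, 2) class weights at each node
    prob1 = counts[:, 1] / counts.sum(axis=1)
    return TreeArrays(
        children_left=t.children_left.copy(),
        children_right=t.children_right.copy(),
        feature=t.feature.copy(),
        threshold=t.threshold.copy(),
        value=prob1 * scale,
        cover=t.weighted_n_node_samples.copy(),
        lte=True,
    )


def _from_xgb_booster(booster) -> list[TreeArrays]:
    df = booster.trees_to_dataframe()
    trees = []
    for _, tdf in df.groupby("Tree", sort=True):
        tdf = tdf.set_index("Node").sort_index()
        n = len(tdf)
        cl = np.full(n, -1, dtype=int)
        cr = np.full(n, -1, dtype=int)
        feat = np.full(n, -1, dtype=int)
        thr = np.zeros(n)
        val = np.zeros(n)
        cov = np.zeros(n)
        node_of = lambda ident: int(ident.split("-")[1])  # noqa: E731
        for node, row in tdf.iterrows():
            cov[node] = row["Cover"]
            if row["Feature"] == "Leaf":
                val[node] = row["Gain"]
            else:
                feat[node] = int(str(row["Feature"]).lstrip("f"))
                thr[node] = row["Split"]
                cl[node] = node_of(row["Yes"])
                cr[node] = node_of(row["No"])
        trees.append(TreeArrays(cl, cr, feat, thr, val, cov, lte=False))
    return trees


# ---------------------------------------------------------------------------
# path-dependent TreeSHAP
# ---------------------------------------------------------------------------


def _extend(m: list[list], pz: float, po: float, pi: int) -> list[list]:
    m = [e.copy() for e in m]
    l = len(m)
    m.append([pi, pz, po, 1.0 if l == 0 else 0.0])
    for j in range(l - 1, -1, -1):
        m[j + 1][3] += po * m[j][3] * (j + 1) / (l + 1)
        m[j][3] = pz * m[j][3] * (l - j) / (l + 1)
    return m


def _unwind(m: list[list], k: int) -> list[list]:
    m = [e.copy() for e in m]
    l = len(m)
    o, z = m[k][2], m[k][1]
    n = m[l - 1][3]
    for j in range(l - 2, -1, -1):
        if o != 0:
            t = m[j][3]
            m[j][3] = n * l / ((j + 1) * o)
            n = t - m[j][3] * z * (l - 1 - j) / l
        else:
            m[j][3] = m[j][3] * l / (z * (l - 1 - j))
    for j in range(k, l - 1):
        m[j][0], m[j][1], m[j][2] = m[j + 1][0], m[j + 1][1], m[j + 1][2]
    m.pop()
    return m


def _unwound_sum(m: list[list], k: int) -> float:
    return float(sum(e[3] for e in _unwind(m, k)))


def _recurse(tree: TreeArrays, node: int, x: np.ndarray, phi: np.ndarray,
             m: list[list], pz: float, po: float, pi: int) -> None:
    m = _extend(m, pz, po, pi)
    if tree.is_leaf(node):
        v = float(tree.value[node])
        for i in range(1, len(m)):
            w = _unwound_sum(m, i)
            phi[m[i][0]] += w * (m[i][2] - m[i][1]) * v
        return
    f = int(tree.feature[node])
    left, right = int(tree.children_left[node]), int(tree.children_right[node])
    hot, cold = (left, right) if tree.goes_left(node, x) else (right, left)
    iz = io = 1.0
    k = next((i for i in range(len(m)) if m[i][0] == f), None)
    if k is not None:
        iz, io = m[k][1], m[k][2]
        m = _unwind(m, k)
    r = float(tree.cover[node])
    _recurse(tree, hot, x, phi, m, iz * float(tree.cover[hot]) / r, io, f)
    _recurse(tree, cold, x, phi, m, iz * float(tree.cover[cold]) / r, 0.0, f)


def tree_shap_values(trees: list[TreeArrays], X: np.ndarray, n_features: int) -> tuple[np.ndarray, float]:
    """(phi matrix (n_samples, n_features), expected ensemble output).

    ``base + phi.sum(axis=1)`` equals the ensemble output for every sample
    (before any base-margin offset).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    phi = np.zeros((X.shape[0], n_features))
    for tree in trees:
        for i, x in enumerate(X):
            _recurse(tree, 0, x, phi[i], [], 1.0, 1.0, -1)
    base = float(sum(t.expectation() for t in trees))
    return phi, base


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def _value_given(tree: TreeArrays, x: np.ndarray, known: frozenset, node: int = 0) -> float:
    """Expectation of the tree output when only features in ``known`` follow x."""
    if tree.is_leaf(node):
        return float(tree.value[node])
    f = int(tree.feature[node])
    left, right = int(tree.children_left[node]), int(tree.children_right[node])
    if f in known:
        nxt = left if tree.goes_left(node, x) else right
        return _value_given(tree, x, known, nxt)
    wl, wr = float(tree.cover[left]), float(tree.cover[right])
    return (
        wl * _value_given(tree, x, known, left) + wr * _value_given(tree, x, known, right)
    ) / (wl + wr)


def brute_force_shapley(tree: TreeArrays, x: np.ndarray, n_features: int) -> np.ndarray:
    """Exact Shapley values by enumerating all feature subsets of one tree."""
    x = np.asarray(x, dtype=float)
    players = sorted({int(f) for f in tree.feature if f >= 0})
    u = len(players)
    phi = np.zeros(n_features)
    for f in players:
        others = [p for p in players if p != f]
        for bits in range(2 ** len(others)):
            s = frozenset(p for j, p in enumerate(others) if bits >> j & 1)
            weight = factorial(len(s)) * factorial(u - len(s) - 1) / factorial(u)
            phi[f] += weight * (
                _value_given(tree, x, s | {f}) - _value_given(tree, x, s)
            )
    return phi
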