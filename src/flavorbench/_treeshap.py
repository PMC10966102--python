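"""Exact path-dependent Shapley attributions for decision-tree ensembles.

Implements the polynomial-time tree-Shapley recursion (Lundberg et al.,
"Consistent individualized feature attribution for tree ensembles"): the
value function of the feature coalition game is the tree-traversal
conditional expectation — at a split on an out-of-coalition feature the
branch values are averaged with training-coverage weights — and the
recursion keeps an extended path of (feature, zero-fraction, one-fraction,
permutation-weight) entries so each leaf contributes its exact Shapley
weight to every feature on its path.

Attributions satisfy local accuracy exactly (up to float rounding):
base + sum(phi) equals the model prediction for every sample.
"""

from __future__ import annotations

import numpy as np

__all__ = ["tree_shap_values", "ensemble_shap_values", "brute_force_tree_shap"]


def _extend(path: list, zero_fraction: float, one_fraction: float,
            feature_index: int) -> None:
    path.append([feature_index, zero_fraction, one_fraction,
                 1.0 if len(path) == 0 else 0.0])
    l = len(path) - 1
    for i in range(l - 1, -1, -1):
        path[i + 1][3] += one_fraction * path[i][3] * (i + 1) / (l + 1)
        path[i][3] = zero_fraction * path[i][3] * (l - i) / (l + 1)


def _unwind(path: list, index: int) -> None:
    l = len(path) - 1
    one_fraction = path[index][2]
    zero_fraction = path[index][1]
    next_one = path[l][3]
    for i in range(l - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = path[i][3]
            path[i][3] = next_one * (l + 1) / ((i + 1) * one_fraction)
            next_one = tmp - path[i][3] * zero_fraction * (l - i) / (l + 1)
        else:
            path[i][3] = path[i][3] * (l + 1) / (zero_fraction * (l - i))
    for i in range(index, l):
        path[i][0], path[i][1], path[i][2] = path[i + 1][0], path[i + 1][1], path[i + 1][2]
    path.pop()


def _unwound_sum(path: list, index: int) -> float:
    l = len(path) - 1
    one_fraction = path[index][2]
    zero_fraction = path[index][1]
    next_one = path[l][3]
    total = 0.0
    for i in range(l - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = next_one * (l + 1) / ((i + 1) * one_fraction)
            total += tmp
            next_one = path[i][3] - tmp * zero_fraction * (l - i) / (l + 1)
        else:
            total += path[i][3] * (l + 1) / (zero_fraction * (l - i))
    return total


def _recurse(arrays, x, phi, node, path, zero_fraction, one_fraction,
             feature_index):
    children_left, children_right, feature, threshold, value, cover = arrays
    path = [entry.copy() for entry in path]
    _extend(path, zero_fraction, one_fraction, feature_index)
    if children_left[node] < 0:  # leaf
        leaf_value = value[node]
        for i in range(1, len(path)):
            w = _unwound_sum(path, i)
            phi[path[i][0]] += w * (path[i][2] - path[i][1]) * leaf_value
        return
    d = feature[node]
    if x[d] <= threshold[node]:
        hot, cold = children_left[node], children_right[node]
    else:
        hot, cold = children_right[node], children_left[node]
    incoming_zero = incoming_one = 1.0
    for k in range(1, len(path)):
        if path[k][0] == d:
            incoming_zero, incoming_one = path[k][1], path[k][2]
            _unwind(path, k)
            break
    r = cover[node]
    _recurse(arrays, x, phi, hot, path,
             incoming_zero * cover[hot] / r, incoming_one, d)
    _recurse(arrays, x, phi, cold, path,
             incoming_zero * cover[cold] / r, 0.0, d)


def tree_shap_values(sk_tree, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Shapley values for one fitted sklearn regression tree.

    Returns (phi with shape (n_samples, n_features), expected value).
    """
    t = sk_tree.tree_
    arrays = (
        t.children_left, t.children_right, t.feature, t.threshold,
        t.value[:, 0, 0].astype(float), t.weighted_n_node_samples.astype(float),
    )
    X = np.asarray(X, dtype=float)
    phi = np.zeros((X.shape[0], X.shape[1]))
    for s in range(X.shape[0]):
        _recurse(arrays, X[s], phi[s], 0, [], 1.0, 1.0, -1)
    expected = float(arrays[4][0])
    return phi, expected


def ensemble_shap_values(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Shapley values for sklearn tree ensembles (and single trees).

    Supports DecisionTreeRegressor, RandomForestRegressor,
    ExtraTreesRegressor (tree average) and GradientBoostingRegressor
    (initial prediction + learning-rate-scaled boosting stages).
    """
    from sklearn.ensemble import (
        ExtraTreesRegressor, GradientBoostingRegressor, RandomForestRegressor,
    )
    from sklearn.tree import DecisionTreeRegressor

    X = np.asarray(X, dtype=float)
    if isinstance(model, DecisionTreeRegressor):
        return tree_shap_values(model, X)
    if isinstance(model, (RandomForestRegressor, ExtraTreesRegressor)):
        phi = np.zeros((X.shape[0], X.shape[1]))
        base = 0.0
        for est in model.estimators_:
            p, e = tree_shap_values(est, X)
            phi += p
            base += e
        n = len(model.estimators_)
        return phi / n, base / n
    if isinstance(model, GradientBoostingRegressor):
        phi = np.zeros((X.shape[0], X.shape[1]))
        base = float(np.ravel(model._raw_predict_init(X[:1]))[0])
        lr = model.learning_rate
        for stage in model.estimators_[:, 0]:
            p, e = tree_shap_values(stage, X)
            phi += lr * p
            base += lr * e
        return phi, base
    raise TypeError(
        f"unsupported model type for tree Shapley: {type(model).__name__}")


# --------------------------------------------------------------------------
# independent oracle (exponential; for testing at small p)
# --------------------------------------------------------------------------

def _tree_conditional_expectation(t, x, coalition: frozenset, node: int = 0) -> float:
    """E[f | x_S] under path-dependent (coverage-weighted) marginalization."""
    if t.children_left[node] < 0:
        return float(t.value[node, 0, 0])
    d = t.feature[node]
    left, right = t.children_left[node], t.children_right[node]
    if d in coalition:
        child = left if x[d] <= t.threshold[node] else right
        return _tree_conditional_expectation(t, x, coalition, child)
    w = t.weighted_n_node_samples
    return (
        w[left] * _tree_conditional_expectation(t, x, coalition, left)
        + w[right] * _tree_conditional_expectation(t, x, coalition, right)
    ) / w[node]


def brute_force_tree_shap(sk_tree, x: np.ndarray) -> np.ndarray:
    """Exact Shapley values by enumerating all 2^p coalitions (p <= ~12)."""
    from itertools import combinations
    from math import factorial

    t = sk_tree.tree_
    x = np.asarray(x, dtype=float)
    p = x.shape[0]
    features = list(range(p))
    phi = np.zeros(p)
    fact = factorial
    for i in features:
        rest = [f for f in features if f != i]
        for size in range(p):
            weight = fact(size) * fact(p - size - 1) / fact(p)
            for subset in combinations(rest, size):
                s = frozenset(subset)
                gain = (_tree_conditional_expectation(t, x, s | {i})
                        - _tree_conditional_expectation(t, x, s))
                phi[i] += weight * gain
    return phi
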