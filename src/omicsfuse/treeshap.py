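"""Exact Shapley attributions for scikit-learn decision trees.

The value function of a feature subset S is the path-dependent conditional
expectation of the tree output: descending the tree, splits on features in S
follow the sample, splits on features outside S average the two subtrees
weighted by their training cover. Shapley values are computed exactly by
enumerating subsets of the features the tree actually splits on (a tree of
depth d uses at most 2^d - 1 distinct features, so enumeration is cheap for
the shallow trees of a boosted ensemble). Attributions are additive across
the trees of a gradient-boosted model and live on its raw (log-odds) scale.
"""

from __future__ import annotations

from math import factorial

import numpy as np

__all__ = ["tree_shap", "boosted_shap"]

_MAX_TREE_FEATURES = 18


def _conditional_expectation(tree, X: np.ndarray, subset: frozenset) -> np.ndarray:
    """E[f(x) | x_S] for every row of X, vectorized over samples."""
    feature = tree.feature
    threshold = tree.threshold
    left, right = tree.children_left, tree.children_right
    value = tree.value.reshape(tree.node_count, -1)[:, 0]
    cover = tree.weighted_n_node_samples

    def rec(node: int) -> np.ndarray:
        if left[node] == -1:  # leaf
            return np.full(X.shape[0], value[node])
        f = feature[node]
        vl, vr = rec(left[node]), rec(right[node])
        if f in subset:
            return np.where(X[:, f] <= threshold[node], vl, vr)
        wl = cover[left[node]] / cover[node]
        return wl * vl + (1.0 - wl) * vr

    return rec(0)


def tree_shap(decision_tree, X: np.ndarray) -> np.ndarray:
    """Exact per-sample Shapley values for one fitted tree.

    Returns an array of shape (n_samples, n_features); features the tree
    never splits on get exactly 0. Satisfies local accuracy:
    ``sum_j phi_j(x) = f(x) - E[f]``.
    """
    t = decision_tree.tree_
    used = np.unique(t.feature[t.feature >= 0])
    if used.size == 0:
        return np.zeros((X.shape[0], X.shape[1]))
    if used.size > _MAX_TREE_FEATURES:
        raise RuntimeError(
            f"tree splits on {used.size} features; exact enumeration is "
            f"limited to {_MAX_TREE_FEATURES} (reduce max_depth)"
        )
    f = used.size
    # conditional expectations for every subset of the used features
    values: dict[frozenset, np.ndarray] = {}
    for mask in range(1 << f):
        S = frozenset(used[i] for i in range(f) if mask >> i & 1)
        values[S] = _conditional_expectation(t, X, S)
    fact = [factorial(i) for i in range(f + 1)]
    phi = np.zeros((X.shape[0], X.shape[1]))
    others = {j: [u for u in used if u != j] for j in used}
    for j in used:
        rest = others[j]
        for mask in range(1 << (f - 1)):
            S = frozenset(rest[i] for i in range(f - 1) if mask >> i & 1)
            s = len(S)
            w = fact[s] * fact[f - s - 1] / fact[f]
            phi[:, j] += w * (values[frozenset(S | {j})] - values[S])
    return phi


def boosted_shap(model, X: np.ndarray) -> np.ndarray:
    """Shapley values of a fitted binary GradientBoostingClassifier.

    Summed over stages and scaled by the learning rate; the result is on the
    raw decision-function (log-odds) scale.
    """
    X = np.ascontiguousarray(X, dtype=float)
    phi = np.zeros((X.shape[0], X.shape[1]))
    for stage in model.estimators_:
        for est in np.atleast_1d(stage).ravel():
            phi += tree_shap(est, X)
    return model.learning_rate * phi
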