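"""Exact Shapley values and interaction values for boosted trees.

Each depth-limited tree touches only a handful of distinct features, so the
conditional expectations v(S) can be enumerated exactly over all subsets S
of the tree's feature set: fixed features follow the record's path (missing
values take the learned default direction) and marginalized features are
averaged over branches weighted by training cover.  This yields the
path-dependent tree-SHAP values with exact local accuracy
(sum(phi) + base == margin) and interaction values whose rows sum to phi.
"""

from __future__ import annotations

from math import factorial

import numpy as np

from .trees import BoostedCoxModel, Tree


def _leaf_paths(tree: Tree):
    """(value, [(feature, is_left, cover_fraction)]) per leaf."""
    paths = []

    def walk(node_id, edges):
        node = tree.nodes[node_id]
        if node.feature < 0:
            paths.append((node.value, list(edges)))
            return
        for child, is_left in ((node.left, True), (node.right, False)):
            frac = tree.nodes[child].cover / max(node.cover, 1e-12)
            edges.append((node.feature, node.threshold, node.default_left, is_left, frac))
            walk(child, edges)
            edges.pop()

    walk(0, [])
    return paths


def _tree_value_table(tree: Tree, X: np.ndarray):
    """v(S) for every subset S of the tree's features, vectorized over rows.

    Returns (features_used, table) where table[mask] is an (n,) vector and
    ``mask`` indexes subsets of features_used.
    """
    used = tree.features_used
    pos = {f: i for i, f in enumerate(used)}
    m = len(used)
    n = X.shape[0]
    table = np.zeros((1 << m, n))
    paths = _leaf_paths(tree)
    # per-edge per-record "follows this edge" indicator
    edge_follow = []
    for value, edges in paths:
        follows = []
        for f, thr, default_left, is_left, frac in edges:
            x = X[:, f]
            goes_left = np.where(np.isnan(x), default_left, x <= thr)
            follows.append((pos[f], np.where(goes_left == is_left, 1.0, 0.0), frac))
        edge_follow.append((value, follows))
    for mask in range(1 << m):
        acc = table[mask]
        for value, follows in edge_follow:
            prod = np.full(n, value)
            for bit, b, frac in follows:
                if mask >> bit & 1:
                    prod = prod * b
                else:
                    prod = prod * frac
            acc += prod
    return used, table


def shap_values(model: BoostedCoxModel, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-record Shapley values; returns (phi matrix, base value)."""
    n, d = X.shape
    phi = np.zeros((n, d))
    base = model.base_margin
    lr = model.learning_rate
    for tree in model.trees:
        used, table = _tree_value_table(tree, X)
        m = len(used)
        # v(empty set) is record-independent: the cover-weighted tree mean
        base += lr * float(table[0][0])
        for i, f in enumerate(used):
            contrib = np.zeros(n)
            others = [j for j in range(m) if j != i]
            for sub in range(1 << (m - 1)):
                mask = 0
                s = 0
                for k, j in enumerate(others):
                    if sub >> k & 1:
                        mask |= 1 << j
                        s += 1
                w = factorial(s) * factorial(m - s - 1) / factorial(m)
                contrib += w * (table[mask | (1 << i)] - table[mask])
            phi[:, f] += lr * contrib
    return phi, base


def shap_interactions(model: BoostedCoxModel, X: np.ndarray) -> np.ndarray:
    """Symmetric per-record interaction matrices (n, d, d).

    Off-diagonal entries carry half the pairwise Shapley interaction; the
    diagonal absorbs the remainder so that each row sums to phi.
    """
    n, d = X.shape
    phi, _ = shap_values(model, X)
    inter = np.zeros((n, d, d))
    lr = model.learning_rate
    for tree in model.trees:
        used, table = _tree_value_table(tree, X)
        m = len(used)
        for i in range(m):
            for j in range(i + 1, m):
                fi, fj = used[i], used[j]
                others = [k for k in range(m) if k not in (i, j)]
                total = np.zeros(n)
                for sub in range(1 << (m - 2) if m >= 2 else 1):
                    mask = 0
                    s = 0
                    for k, o in enumerate(others):
                        if sub >> k & 1:
                            mask |= 1 << o
                            s += 1
                    w = factorial(s) * factorial(m - s - 2) / factorial(m - 1)
                    total += w * (
                        table[mask | (1 << i) | (1 << j)]
                        - table[mask | (1 << i)]
                        - table[mask | (1 << j)]
                        + table[mask]
                    )
                inter[:, fi, fj] += lr * 0.5 * total
                inter[:, fj, fi] += lr * 0.5 * total
    # diagonal: main effect = phi minus allocated interactions
    for f in range(d):
        inter[:, f, f] = phi[:, f] - (inter[:, f, :].sum(axis=1) - inter[:, f, f])
    return inter
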