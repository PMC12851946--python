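"""Regression trees and Cox-objective gradient boosting.

Small CART-style trees with second-order (gradient/hessian) split gain,
native missing-value handling via learned default directions, boosted
against the Breslow partial-likelihood of a right-censored composite
endpoint.  The model maximizes rank concordance between its margin and the
event ordering, which is what the concordance index measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TreeNode:
    feature: int = -1          # -1 for leaves
    threshold: float = np.nan
    default_left: bool = True
    left: int = -1
    right: int = -1
    value: float = 0.0
    cover: float = 0.0         # training sample count reaching the node


@dataclass
class Tree:
    nodes: list[TreeNode] = field(default_factory=list)

    def _arrays(self):
        if not hasattr(self, "_arr"):
            n = len(self.nodes)
            self._arr = dict(
                feature=np.array([nd.feature for nd in self.nodes]),
                threshold=np.array([nd.threshold for nd in self.nodes]),
                default_left=np.array([nd.default_left for nd in self.nodes]),
                left=np.array([nd.left for nd in self.nodes]),
                right=np.array([nd.right for nd in self.nodes]),
                value=np.array([nd.value for nd in self.nodes]),
            )
        return self._arr

    def predict(self, X: np.ndarray) -> np.ndarray:
        a = self._arrays()
        cur = np.zeros(X.shape[0], dtype=int)
        while True:
            feat = a["feature"][cur]
            internal = feat >= 0
            if not internal.any():
                break
            rows = np.flatnonzero(internal)
            x = X[rows, feat[rows]]
            thr = a["threshold"][cur[rows]]
            go_left = np.where(np.isnan(x), a["default_left"][cur[rows]], x <= thr)
            cur[rows] = np.where(go_left, a["left"][cur[rows]], a["right"][cur[rows]])
        return a["value"][cur]

    @property
    def features_used(self) -> list[int]:
        return sorted({n.feature for n in self.nodes if n.feature >= 0})


def _leaf_value(g_sum: float, h_sum: float, reg_lambda: float) -> float:
    return -g_sum / (h_sum + reg_lambda)


def _best_split(X, g, h, idx, feature, reg_lambda, min_leaf):
    """Best (gain, threshold, default_left) for one feature on one node."""
    x = X[idx, feature]
    miss = np.isnan(x)
    obs = ~miss
    if obs.sum() < 2 * min_leaf:
        return None
    xv = x[obs]
    gv, hv = g[idx][obs], h[idx][obs]
    g_miss, h_miss = g[idx][miss].sum(), h[idx][miss].sum()
    n_miss = int(miss.sum())
    order = np.argsort(xv, kind="stable")
    xv, gv, hv = xv[order], gv[order], hv[order]
    g_tot, h_tot = gv.sum() + g_miss, hv.sum() + h_miss
    parent = g_tot**2 / (h_tot + reg_lambda)
    gc, hc = np.cumsum(gv), np.cumsum(hv)
    # candidate cuts between distinct consecutive values
    cuts = np.flatnonzero(xv[1:] > xv[:-1])
    if cuts.size == 0:
        return None
    n_left = cuts + 1
    n_right = len(xv) - n_left
    gl, hl = gc[cuts], hc[cuts]
    gr, hr = gc[-1] - gl, hc[-1] - hl
    best = None
    for default_left in (True, False):
        if default_left:
            gl2, hl2, nl = gl + g_miss, hl + h_miss, n_left + n_miss
            gr2, hr2, nr = gr, hr, n_right
        else:
            gl2, hl2, nl = gl, hl, n_left
            gr2, hr2, nr = gr + g_miss, hr + h_miss, n_right + n_miss
        gain = gl2**2 / (hl2 + reg_lambda) + gr2**2 / (hr2 + reg_lambda) - parent
        ok = (nl >= min_leaf) & (nr >= min_leaf)
        if not ok.any():
            continue
        gain = np.where(ok, gain, -np.inf)
        k = int(np.argmax(gain))
        if best is None or gain[k] > best[0]:
            best = (float(gain[k]), 0.5 * (xv[cuts[k]] + xv[cuts[k] + 1]), default_left)
    return best


def build_tree(
    X: np.ndarray,
    g: np.ndarray,
    h: np.ndarray,
    idx: np.ndarray,
    max_depth: int = 3,
    min_samples_leaf: int = 10,
    reg_lambda: float = 1.0,
    min_gain: float = 1e-6,
) -> Tree:
    """Greedy depth-limited tree on gradient/hessian statistics."""
    tree = Tree()

    def grow(sample_idx, depth):
        node_id = len(tree.nodes)
        g_sum, h_sum = g[sample_idx].sum(), h[sample_idx].sum()
        node = TreeNode(value=_leaf_value(g_sum, h_sum, reg_lambda), cover=float(len(sample_idx)))
        tree.nodes.append(node)
        if depth >= max_depth or len(sample_idx) < 2 * min_samples_leaf:
            return node_id
        best = None
        for f in range(X.shape[1]):
            cand = _best_split(X, g, h, sample_idx, f, reg_lambda, min_samples_leaf)
            if cand is not None and (best is None or cand[0] > best[1][0]):
                best = (f, cand)
        if best is None or best[1][0] <= min_gain:
            return node_id
        f, (gain, thr, default_left) = best
        x = X[sample_idx, f]
        miss = np.isnan(x)
        goes_left = np.where(miss, default_left, x <= thr)
        node.feature = f
        node.threshold = thr
        node.default_left = default_left
        node.left = grow(sample_idx[goes_left], depth + 1)
        node.right = grow(sample_idx[~goes_left], depth + 1)
        return node_id

    grow(np.asarray(idx), 0)
    return tree


def cox_gradients(margin: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Breslow partial-likelihood gradient and hessian diagonal.

    Returns (g, h) for the negative log partial likelihood of the margin.
    """
    n = len(margin)
    order = np.argsort(time, kind="stable")
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    t_s = time[order]
    e_s = event[order]
    m_s = margin[order]
    w = np.exp(m_s - m_s.max())
    # risk-set sums: S_k = sum of w over t_j >= t_k (ties share the risk set)
    suffix = np.cumsum(w[::-1])[::-1]
    risk_sum = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_s[j + 1] == t_s[i]:
            j += 1
        risk_sum[i : j + 1] = suffix[i]
        i = j + 1
    inv_s = np.where(e_s == 1, 1.0 / risk_sum, 0.0)
    inv_s2 = np.where(e_s == 1, 1.0 / risk_sum**2, 0.0)
    # prefix sums over event times with t_k <= t_i (tie groups included fully)
    c1 = np.cumsum(inv_s)
    c2 = np.cumsum(inv_s2)
    a1 = np.empty(n)
    a2 = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_s[j + 1] == t_s[i]:
            j += 1
        a1[i : j + 1] = c1[j]
        a2[i : j + 1] = c2[j]
        i = j + 1
    g_s = -e_s + w * a1
    h_s = w * a1 - w**2 * a2
    h_s = np.maximum(h_s, 1e-12)
    return g_s[inv], h_s[inv]


@dataclass
class BoostedCoxModel:
    trees: list[Tree] = field(default_factory=list)
    learning_rate: float = 0.1
    base_margin: float = 0.0

    def margin(self, X: np.ndarray) -> np.ndarray:
        out = np.full(X.shape[0], self.base_margin)
        for tree in self.trees:
            out += self.learning_rate * tree.predict(X)
        return out


def fit_boosted_cox(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    n_trees: int = 150,
    learning_rate: float = 0.1,
    max_depth: int = 3,
    min_samples_leaf: int = 10,
    reg_lambda: float = 1.0,
    subsample: float = 0.8,
    seed: int = 0,
) -> BoostedCoxModel:
    """Gradient boosting of Cox partial likelihood with row subsampling."""
    if event.sum() < 1:
        raise ValueError("need at least one event to fit a survival objective")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    model = BoostedCoxModel(learning_rate=learning_rate)
    margin = np.zeros(n)
    for _ in range(n_trees):
        g, h = cox_gradients(margin, time, event)
        if subsample < 1.0:
            idx = rng.choice(n, size=max(2 * min_samples_leaf, int(subsample * n)), replace=False)
        else:
            idx = np.arange(n)
        tree = build_tree(
            X, g, h, idx,
            max_depth=max_depth,
            min_samples_leaf=min_samples_leaf,
            reg_lambda=reg_lambda,
        )
        model.trees.append(tree)
        margin += learning_rate * tree.predict(X)
    return model
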