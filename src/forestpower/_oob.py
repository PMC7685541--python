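"""Numba kernels for out-of-bag permutation importance.

For each tree, prediction error on that tree's OOB samples is compared
with the error after permuting one feature's OOB values at a time; only
features actually used by the tree's split nodes are traversed (all
others have exactly zero contribution).  Losses are MSE (regression) and
misclassification rate (classification); the per-tree contribution is
the loss increase, averaged over all trees of the forest.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["tree_perm_increase_reg", "tree_perm_increase_clf"]


@njit(cache=True)
def tree_perm_increase_reg(children_left, children_right, feature, threshold,
                           leaf_value, Xo, yo, used, perms):
    """Per-feature MSE increase on OOB rows for one regression tree.

    ``used`` holds the feature indices appearing in the tree's splits;
    ``perms[k]`` is a row permutation applied to feature ``used[k]``.
    Returns (base_mse, increases aligned with ``used``).
    """
    m = Xo.shape[0]
    k = used.shape[0]
    base_se = 0.0
    for s in range(m):
        node = 0
        while children_left[node] != -1:
            if Xo[s, feature[node]] <= threshold[node]:
                node = children_left[node]
            else:
                node = children_right[node]
        d = leaf_value[node] - yo[s]
        base_se += d * d
    base = base_se / m
    out = np.empty(k)
    for ki in range(k):
        f = used[ki]
        se = 0.0
        for s in range(m):
            node = 0
            while children_left[node] != -1:
                fn = feature[node]
                if fn == f:
                    xv = Xo[perms[ki, s], fn]
                else:
                    xv = Xo[s, fn]
                if xv <= threshold[node]:
                    node = children_left[node]
                else:
                    node = children_right[node]
            d = leaf_value[node] - yo[s]
            se += d * d
        out[ki] = se / m - base
    return base, out


@njit(cache=True)
def tree_perm_increase_clf(children_left, children_right, feature, threshold,
                           leaf_class, Xo, yo, used, perms):
    """Per-feature error-rate increase (mean decrease accuracy) for one tree."""
    m = Xo.shape[0]
    k = used.shape[0]
    base_err = 0.0
    for s in range(m):
        node = 0
        while children_left[node] != -1:
            if Xo[s, feature[node]] <= threshold[node]:
                node = children_left[node]
            else:
                node = children_right[node]
        if leaf_class[node] != yo[s]:
            base_err += 1.0
    base = base_err / m
    out = np.empty(k)
    for ki in range(k):
        f = used[ki]
        err = 0.0
        for s in range(m):
            node = 0
            while children_left[node] != -1:
                fn = feature[node]
                if fn == f:
                    xv = Xo[perms[ki, s], fn]
                else:
                    xv = Xo[s, fn]
                if xv <= threshold[node]:
                    node = children_left[node]
                else:
                    node = children_right[node]
            if leaf_class[node] != yo[s]:
                err += 1.0
        out[ki] = err / m - base
    return base, out
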