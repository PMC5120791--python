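"""Compiled CART kernels.

The tree representation is flat: parallel arrays indexed by node id, with
``feature[nid] == -1`` marking a leaf.  Categorical predictors are passed as
non-negative integer level codes stored in the float design matrix; a
categorical split sends a row left when the bit of its level code is set in
``cat_mask[nid]`` (level codes must therefore stay below 63).

Split search maximises the reduction in within-node sum of squared errors of
the constant fit.  For a categorical variable the optimal level subset is
found by ordering levels by their mean response and scanning the cut
positions of that ordering, which is exact for squared-error regression.

Tie-breaking is deterministic: candidate variables are scanned in ascending
column order and, within a numeric variable, thresholds in ascending order;
only a strictly larger reduction displaces the incumbent, so the first
maximiser wins.  A split must beat a tiny relative gain floor, which rejects
numerically-zero gains on constant responses.
"""

import numpy as np
from numba import njit

NUMERIC = 0
CATEGORICAL = 1


@njit(cache=True)
def best_split_node(X, y, idx, lo, hi, cand, kinds, n_levels):
    """Best split for rows ``idx[lo:hi]`` over candidate columns ``cand``.

    Returns ``(var, threshold, cat_mask, sse_reduction)``; ``var == -1``
    means no admissible split (constant response or constant candidates).
    ``cand`` must be sorted ascending for the tie-break rule to apply.
    """
    n = hi - lo
    s = 0.0
    ss = 0.0
    for k in range(lo, hi):
        v = y[idx[k]]
        s += v
        ss += v * v
    parent = ss - s * s / n
    floor = 1e-12 * (parent if parent > 1.0 else 1.0)
    best_var = -1
    best_thr = np.nan
    best_mask = np.int64(0)
    best_red = floor
    for ci in range(cand.shape[0]):
        j = cand[ci]
        if kinds[j] == NUMERIC:
            vals = np.empty(n)
            for k in range(n):
                vals[k] = X[idx[lo + k], j]
            order = np.argsort(vals)
            ls = 0.0
            lss = 0.0
            for k in range(n - 1):
                r = y[idx[lo + order[k]]]
                ls += r
                lss += r * r
                if vals[order[k + 1]] <= vals[order[k]]:
                    continue
                nl = float(k + 1)
                nr = float(n - k - 1)
                rs = s - ls
                rss = ss - lss
                red = parent - (lss - ls * ls / nl) - (rss - rs * rs / nr)
                if red > best_red:
                    best_red = red
                    best_var = j
                    best_thr = 0.5 * (vals[order[k]] + vals[order[k + 1]])
                    best_mask = np.int64(0)
        else:
            L = n_levels[j]
            cnt = np.zeros(L)
            sm = np.zeros(L)
            sq = np.zeros(L)
            for k in range(lo, hi):
                lev = int(X[idx[k], j])
                cnt[lev] += 1.0
                sm[lev] += y[idx[k]]
                sq[lev] += y[idx[k]] * y[idx[k]]
            codes = np.empty(L, np.int64)
            npres = 0
            for lev in range(L):
                if cnt[lev] > 0.0:
                    codes[npres] = lev
                    npres += 1
            # insertion sort of present levels by mean response, ties by code
            for a in range(1, npres):
                ca = codes[a]
                ma = sm[ca] / cnt[ca]
                b = a - 1
                while b >= 0:
                    cb = codes[b]
                    mb = sm[cb] / cnt[cb]
                    if mb > ma or (mb == ma and cb > ca):
                        codes[b + 1] = cb
                        b -= 1
                    else:
                        break
                codes[b + 1] = ca
            ls = 0.0
            lss = 0.0
            lc = 0.0
            mask = np.int64(0)
            for a in range(npres - 1):
                c0 = codes[a]
                ls += sm[c0]
                lss += sq[c0]
                lc += cnt[c0]
                mask |= np.int64(1) << c0
                nr = float(n) - lc
                rs = s - ls
                rss = ss - lss
                red = parent - (lss - ls * ls / lc) - (rss - rs * rs / nr)
                if red > best_red:
                    best_red = red
                    best_var = j
                    best_thr = np.nan
                    best_mask = mask
    if best_var < 0:
        return -1, np.nan, np.int64(0), 0.0
    return best_var, best_thr, best_mask, best_red


@njit(cache=True)
def grow_tree(X, y, kinds, n_levels, sample_idx, m, n_min, var_keys,
              feature, threshold, cat_mask, left, right, value, node_size):
    """Grow one regression tree in place; returns the number of nodes used.

    ``sample_idx`` is the (possibly bootstrapped) multiset of training rows.
    ``var_keys[nid]`` holds uniform random keys; at each splittable node the
    ``m`` columns with the smallest keys form the candidate set, which makes
    the per-node variable draw a function of the node id alone (node ids are
    assigned in a deterministic depth-first order), independent of row order.
    A node is split only when it holds at least ``n_min`` rows and the best
    split strictly reduces the sum of squared errors.
    """
    p = X.shape[1]
    idx = sample_idx.copy()
    cap = feature.shape[0]
    st_node = np.empty(cap, np.int64)
    st_lo = np.empty(cap, np.int64)
    st_hi = np.empty(cap, np.int64)
    st_node[0] = 0
    st_lo[0] = 0
    st_hi[0] = idx.shape[0]
    top = 1
    node_count = 1
    cand = np.empty(m, np.int64)
    used = np.empty(p, np.bool_)
    while top > 0:
        top -= 1
        nid = st_node[top]
        lo = st_lo[top]
        hi = st_hi[top]
        n = hi - lo
        s = 0.0
        for k in range(lo, hi):
            s += y[idx[k]]
        value[nid] = s / n
        feature[nid] = -1
        threshold[nid] = np.nan
        cat_mask[nid] = 0
        left[nid] = -1
        right[nid] = -1
        node_size[nid] = n
        if n < n_min:
            continue
        # m distinct columns with the smallest random keys, ascending order
        for j in range(p):
            used[j] = False
        for _ in range(m):
            bj = -1
            bk = np.inf
            for j in range(p):
                if not used[j] and var_keys[nid, j] < bk:
                    bk = var_keys[nid, j]
                    bj = j
            used[bj] = True
        ci = 0
        for j in range(p):
            if used[j]:
                cand[ci] = j
                ci += 1
        var, thr, mask, red = best_split_node(X, y, idx, lo, hi, cand,
                                              kinds, n_levels)
        if var < 0:
            continue
        i = lo
        jj = hi - 1
        if kinds[var] == NUMERIC:
            while i <= jj:
                if X[idx[i], var] <= thr:
                    i += 1
                else:
                    tmp = idx[i]
                    idx[i] = idx[jj]
                    idx[jj] = tmp
                    jj -= 1
        else:
            while i <= jj:
                lev = int(X[idx[i], var])
                if (mask >> lev) & 1:
                    i += 1
                else:
                    tmp = idx[i]
                    idx[i] = idx[jj]
                    idx[jj] = tmp
                    jj -= 1
        mid = i
        if mid == lo or mid == hi:
            continue
        feature[nid] = var
        threshold[nid] = thr
        cat_mask[nid] = mask
        lid = node_count
        rid = node_count + 1
        node_count += 2
        left[nid] = lid
        right[nid] = rid
        st_node[top] = rid
        st_lo[top] = mid
        st_hi[top] = hi
        top += 1
        st_node[top] = lid
        st_lo[top] = lo
        st_hi[top] = mid
        top += 1
    return node_count


@njit(cache=True)
def apply_tree(X, kinds, feature, threshold, cat_mask, left, right, out):
    """Leaf node id reached by every row of ``X``."""
    for i in range(X.shape[0]):
        nid = 0
        while feature[nid] >= 0:
            j = feature[nid]
            if kinds[j] == NUMERIC:
                if X[i, j] <= threshold[nid]:
                    nid = left[nid]
                else:
                    nid = right[nid]
            else:
                lev = int(X[i, j])
                if (cat_mask[nid] >> lev) & 1:
                    nid = left[nid]
                else:
                    nid = right[nid]
        out[i] = nid


@njit(cache=True)
def accumulate_tree_prediction(X, kinds, feature, threshold, cat_mask,
                               left, right, value, out):
    """Add this tree's prediction for every row of ``X`` into ``out``."""
    for i in range(X.shape[0]):
        nid = 0
        while feature[nid] >= 0:
            j = feature[nid]
            if kinds[j] == NUMERIC:
                if X[i, j] <= threshold[nid]:
                    nid = left[nid]
                else:
                    nid = right[nid]
            else:
                lev = int(X[i, j])
                if (cat_mask[nid] >> lev) & 1:
                    nid = left[nid]
                else:
                    nid = right[nid]
        out[i] += value[nid]
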