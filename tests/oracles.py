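"""Independent brute-force oracles used to validate the compiled CART
implementation.  Everything here is deliberately slow and simple: splits
are found by enumerating every variable and every cut position and
recomputing sums from scratch."""

import numpy as np


def _sse(y):
    if len(y) == 0:
        return 0.0
    m = sum(y) / len(y)
    return sum((v - m) ** 2 for v in y)


def brute_force_best_split(X, y):
    """Exhaustive best SSE-reducing split on an all-numeric matrix.

    Scans variables in column order and thresholds ascending; only a
    strictly larger reduction displaces the incumbent, and the reduction
    must clear a tiny relative floor.  Returns (j, threshold, reduction)
    or None.
    """
    X = np.asarray(X, dtype=float)
    y = list(map(float, y))
    n = len(y)
    parent = _sse(y)
    floor = 1e-12 * max(parent, 1.0)
    best = None
    best_red = floor
    for j in range(X.shape[1]):
        vals = sorted(set(X[:, j]))
        for a, b in zip(vals, vals[1:]):
            thr = 0.5 * (a + b)
            left = [y[i] for i in range(n) if X[i, j] <= thr]
            right = [y[i] for i in range(n) if X[i, j] > thr]
            red = parent - _sse(left) - _sse(right)
            if red > best_red:
                best_red = red
                best = (j, thr, red)
    return best


def brute_force_cart(X, y, n_min):
    """Recursive exhaustive CART on an all-numeric matrix.

    Returns a nested tuple: ("leaf", mean, n) or
    ("split", j, threshold, left_subtree, right_subtree).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    mean = float(np.sum(y) / n)
    if n < n_min:
        return ("leaf", mean, n)
    found = brute_force_best_split(X, y)
    if found is None:
        return ("leaf", mean, n)
    j, thr, _ = found
    lmask = X[:, j] <= thr
    return ("split", j, thr,
            brute_force_cart(X[lmask], y[lmask], n_min),
            brute_force_cart(X[~lmask], y[~lmask], n_min))


def brute_force_partition(X, y, n_min):
    """Leaf partition of the training rows under exhaustive CART: a set of
    (frozenset(row indices), leaf mean) pairs.  Exactly tied splits (which
    for continuous data arise only when two variables induce the same row
    partition) leave the partition unchanged, so this is the
    tie-robust object to compare implementations on."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    leaves = []

    def walk(idx):
        n = len(idx)
        mean = float(np.sum(y[idx]) / n)
        if n < n_min:
            leaves.append((frozenset(idx.tolist()), mean))
            return
        found = brute_force_best_split(X[idx], y[idx])
        if found is None:
            leaves.append((frozenset(idx.tolist()), mean))
            return
        j, thr, _ = found
        lmask = X[idx, j] <= thr
        walk(idx[lmask])
        walk(idx[~lmask])

    walk(np.arange(len(y)))
    return leaves


def assert_same_partition(tree, df, brute_leaves, tol=1e-9):
    """The package tree's leaf partition of the training rows, and the leaf
    means, match the brute-force oracle's."""
    assignments = tree.apply(df)
    got = {}
    for leaf in np.unique(assignments):
        rows = frozenset(np.flatnonzero(assignments == leaf).tolist())
        got[rows] = float(tree.value[leaf])
    want = {rows: mean for rows, mean in brute_leaves}
    assert set(got) == set(want), (
        f"leaf partitions differ: {sorted(map(sorted, got))} vs "
        f"{sorted(map(sorted, want))}")
    for rows, mean in want.items():
        assert abs(got[rows] - mean) <= tol, \
            f"leaf mean differs on rows {sorted(rows)}"


def tree_to_nested(tree):
    """Flatten-array RegressionTree -> the same nested-tuple shape the
    brute-force oracle produces (numeric splits only)."""
    def build(nid):
        if tree.feature[nid] < 0:
            return ("leaf", float(tree.value[nid]), int(tree.node_size[nid]))
        return ("split", int(tree.feature[nid]), float(tree.threshold[nid]),
                build(int(tree.left[nid])), build(int(tree.right[nid])))
    return build(0)


def assert_trees_equal(nested_a, nested_b, tol=1e-9):
    """Structural equality of two nested trees: same split variables and
    thresholds, leaf means equal to within ``tol``."""
    if nested_a[0] != nested_b[0]:
        raise AssertionError(f"node kinds differ: {nested_a[0]} vs "
                             f"{nested_b[0]}")
    if nested_a[0] == "leaf":
        assert abs(nested_a[1] - nested_b[1]) <= tol, \
            f"leaf means differ: {nested_a[1]} vs {nested_b[1]}"
        assert nested_a[2] == nested_b[2], "leaf sizes differ"
        return
    assert nested_a[1] == nested_b[1], \
        f"split variables differ: {nested_a[1]} vs {nested_b[1]}"
    assert abs(nested_a[2] - nested_b[2]) <= tol, "thresholds differ"
    assert_trees_equal(nested_a[3], nested_b[3], tol)
    assert_trees_equal(nested_a[4], nested_b[4], tol)


def leaf_regions(tree):
    """Enumerate every leaf's region as interval constraints per numeric
    column and allowed-level sets per categorical column."""
    p = len(tree.encoding.columns)
    kinds = tree.encoding.kinds
    regions = []

    def walk(nid, lo, hi, allowed):
        if tree.feature[nid] < 0:
            regions.append((dict(lo), dict(hi),
                            {k: set(v) for k, v in allowed.items()}))
            return
        j = int(tree.feature[nid])
        if kinds[j] == 0:
            thr = float(tree.threshold[nid])
            lo2, hi2 = dict(lo), dict(hi)
            hi2[j] = min(hi.get(j, np.inf), thr)
            walk(int(tree.left[nid]), lo, hi2, allowed)
            lo2[j] = max(lo.get(j, -np.inf), thr)
            walk(int(tree.right[nid]), lo2, hi, allowed)
        else:
            mask = int(tree.cat_mask[nid])
            name = tree.encoding.columns[j]
            levels = set(range(len(tree.encoding.levels[name])))
            inmask = {lev for lev in levels if (mask >> lev) & 1}
            a2 = {k: set(v) for k, v in allowed.items()}
            a2[j] = allowed.get(j, levels) & inmask
            walk(int(tree.left[nid]), lo, hi, a2)
            a3 = {k: set(v) for k, v in allowed.items()}
            a3[j] = allowed.get(j, levels) - inmask
            walk(int(tree.right[nid]), lo, hi, a3)

    walk(0, {}, {}, {})
    return regions


def region_contains(region, x, kinds):
    lo, hi, allowed = region
    for j, bound in lo.items():
        if not x[j] > bound:
            return False
    for j, bound in hi.items():
        if not x[j] <= bound:
            return False
    for j, levs in allowed.items():
        if int(x[j]) not in levs:
            return False
    return True
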