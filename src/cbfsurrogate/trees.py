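"""Regression trees and bagged forests for mixed clinical data.

Implements CART-style recursive partitioning from scratch: each split
minimises the within-node sum of squared errors of a constant fit, leaves
carry the mean response of their region, and a forest averages ``T`` trees,
each grown on an independent bootstrap resample of the ``N`` training rows
with ``m`` candidate predictors drawn uniformly without replacement at every
node.  Defaults (``T=500, m=3, n_min=5``) match the study configuration for
an 11-predictor clinical table.

Numeric thresholds sit at midpoints between consecutive distinct sorted
values.  Categorical predictors split on level subsets; the optimal subset
is found exactly by ordering levels by mean response.  Ties between splits
are broken toward the earlier column in the table schema, then the smaller
threshold, so fits are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels

__all__ = [
    "ForestParams",
    "SplitDecision",
    "RegressionTree",
    "Forest",
    "encode_frame",
    "best_split",
    "grow_tree",
    "fit_forest",
    "predict_forest",
]

_MAX_LEVELS = 63  # categorical level codes live in an int64 bitmask


class MissingValueError(ValueError):
    """Raised when a tree/forest fit or prediction sees missing values."""


@dataclass(frozen=True)
class ForestParams:
    """Forest hyperparameters: ensemble size T, per-node candidate count m,
    minimum node size for splitting, and whether trees see bootstrap
    resamples (disable only for testing/degenerate ensembles)."""

    n_trees: int = 500
    m: int = 3
    n_min: int = 5
    bootstrap: bool = True

    def validate(self, p: int) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 1 <= self.m <= p:
            raise ValueError(f"m must be in [1, p={p}], got {self.m}")
        if self.n_min < 1:
            raise ValueError("n_min must be >= 1")


@dataclass(frozen=True)
class SplitDecision:
    """One binary split: numeric rows go left when value <= threshold;
    categorical rows go left when their level is in ``levels_left``."""

    variable: str
    kind: str  # "numeric" | "categorical"
    threshold: float | None
    levels_left: frozenset | None
    sse_reduction: float


class _Encoding:
    """Column metadata shared by trees of a fit: names, numeric/categorical
    kind flags and, for categorical columns, the ordered observed levels
    whose positions serve as integer codes."""

    def __init__(self, columns, kinds, levels):
        self.columns = list(columns)
        self.kinds = np.asarray(kinds, dtype=np.int8)
        self.levels = {k: list(v) for k, v in levels.items()}

    @property
    def n_levels(self) -> np.ndarray:
        out = np.zeros(len(self.columns), dtype=np.int64)
        for j, c in enumerate(self.columns):
            if self.kinds[j] == _kernels.CATEGORICAL:
                out[j] = len(self.levels[c])
        return out

    def encode(self, df: pd.DataFrame) -> np.ndarray:
        X = np.empty((len(df), len(self.columns)), dtype=np.float64)
        for j, c in enumerate(self.columns):
            col = df[c]
            if self.kinds[j] == _kernels.NUMERIC:
                X[:, j] = pd.to_numeric(col).to_numpy(dtype=np.float64)
            else:
                lut = {lev: float(i) for i, lev in enumerate(self.levels[c])}
                vals = np.empty(len(df), dtype=np.float64)
                for i, v in enumerate(col.to_numpy()):
                    if pd.isna(v):
                        vals[i] = np.nan
                    elif v in lut:
                        vals[i] = lut[v]
                    else:
                        raise ValueError(
                            f"unseen level {v!r} in column {c!r}")
                X[:, j] = vals
        return X

    def to_dict(self):
        return {"columns": self.columns,
                "kinds": self.kinds.tolist(),
                "levels": self.levels}

    @classmethod
    def from_dict(cls, d):
        return cls(d["columns"], d["kinds"], d["levels"])


def encode_frame(df: pd.DataFrame, columns=None) -> tuple[np.ndarray, "_Encoding"]:
    """Encode a mixed-type frame as a float design matrix.

    Numeric columns pass through; object/category/bool columns become level
    codes over their sorted observed levels (at most 63 levels).  Missing
    cells become NaN — fitting rejects them, the imputation module owns them.
    """
    if columns is None:
        columns = list(df.columns)
    kinds = []
    levels = {}
    for c in columns:
        col = df[c]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            kinds.append(_kernels.NUMERIC)
        else:
            obs = sorted({v for v in col.dropna().unique()}, key=str)
            if len(obs) > _MAX_LEVELS:
                raise ValueError(
                    f"column {c!r} has {len(obs)} levels; max {_MAX_LEVELS}")
            kinds.append(_kernels.CATEGORICAL)
            levels[c] = obs
    enc = _Encoding(columns, kinds, levels)
    return enc.encode(df), enc


@dataclass
class RegressionTree:
    """Flat-array regression tree.  ``feature[nid] == -1`` marks a leaf whose
    prediction is ``value[nid]`` (the mean response of its training region);
    internal nodes route numeric values by threshold and categorical level
    codes by the ``cat_mask`` bitmask."""

    encoding: _Encoding
    feature: np.ndarray
    threshold: np.ndarray
    cat_mask: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    node_size: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    @property
    def n_leaves(self) -> int:
        return int(np.sum(self.feature < 0))

    def leaf_values(self) -> np.ndarray:
        return self.value[self.feature < 0]

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = self.encoding.encode(X)
        X = np.asarray(X, dtype=np.float64)
        if np.isnan(X).any():
            raise MissingValueError(
                "prediction inputs contain missing values; impute first "
                "(see cbfsurrogate.imputation)")
        return X

    def apply(self, X) -> np.ndarray:
        """Leaf node id reached by each row."""
        X = self._matrix(X)
        out = np.empty(len(X), dtype=np.int64)
        _kernels.apply_tree(X, self.encoding.kinds, self.feature,
                            self.threshold, self.cat_mask, self.left,
                            self.right, out)
        return out

    def predict(self, X) -> np.ndarray:
        X = self._matrix(X)
        out = np.zeros(len(X))
        _kernels.accumulate_tree_prediction(
            X, self.encoding.kinds, self.feature, self.threshold,
            self.cat_mask, self.left, self.right, self.value, out)
        return out

    def split_decisions(self) -> list[SplitDecision]:
        """All internal-node splits in node-id order."""
        out = []
        for nid in range(self.n_nodes):
            j = self.feature[nid]
            if j < 0:
                continue
            out.append(_decision_from_arrays(
                self.encoding, int(j), float(self.threshold[nid]),
                int(self.cat_mask[nid]), np.nan))
        return out

    def to_dict(self) -> dict:
        def build(nid):
            if self.feature[nid] < 0:
                return {"leaf": True, "value": float(self.value[nid]),
                        "n": int(self.node_size[nid])}
            j = int(self.feature[nid])
            name = self.encoding.columns[j]
            node = {"leaf": False, "variable": name,
                    "n": int(self.node_size[nid]),
                    "left": build(int(self.left[nid])),
                    "right": build(int(self.right[nid]))}
            if self.encoding.kinds[j] == _kernels.NUMERIC:
                node["threshold"] = float(self.threshold[nid])
            else:
                mask = int(self.cat_mask[nid])
                node["levels_left"] = [
                    lev for i, lev in enumerate(self.encoding.levels[name])
                    if (mask >> i) & 1]
            return node
        return build(0)

    @classmethod
    def from_dict(cls, d: dict, encoding: _Encoding) -> "RegressionTree":
        nodes = []

        def walk(node):
            nid = len(nodes)
            nodes.append(None)
            if node["leaf"]:
                nodes[nid] = (-1, np.nan, 0, -1, -1, node["value"], node["n"])
                return nid
            j = encoding.columns.index(node["variable"])
            if encoding.kinds[j] == _kernels.NUMERIC:
                thr, mask = node["threshold"], 0
            else:
                thr = np.nan
                idx = {lev: i for i, lev in
                       enumerate(encoding.levels[node["variable"]])}
                mask = 0
                for lev in node["levels_left"]:
                    mask |= 1 << idx[lev]
            lid = walk(node["left"])
            rid = walk(node["right"])
            # leaf value of internal node is unused at prediction time
            nodes[nid] = (j, thr, mask, lid, rid, 0.0, node["n"])
            return nid

        walk(d)
        arr = list(zip(*nodes))
        return cls(encoding,
                   np.array(arr[0], dtype=np.int64),
                   np.array(arr[1], dtype=np.float64),
                   np.array(arr[2], dtype=np.int64),
                   np.array(arr[3], dtype=np.int64),
                   np.array(arr[4], dtype=np.int64),
                   np.array(arr[5], dtype=np.float64),
                   np.array(arr[6], dtype=np.int64))


def _decision_from_arrays(enc, j, thr, mask, red) -> SplitDecision:
    name = enc.columns[j]
    if enc.kinds[j] == _kernels.NUMERIC:
        return SplitDecision(name, "numeric", thr, None, red)
    levs = frozenset(lev for i, lev in enumerate(enc.levels[name])
                     if (mask >> i) & 1)
    return SplitDecision(name, "categorical", None, levs, red)


def _check_complete(X: np.ndarray) -> None:
    if np.isnan(X).any():
        raise MissingValueError(
            "training table contains missing values; run "
            "cbfsurrogate.imputation.impute first")


def best_split(table: pd.DataFrame, y, candidate_vars=None):
    """Exhaustive best split of one node over ``candidate_vars``.

    Returns a :class:`SplitDecision`, or ``None`` when no split strictly
    reduces the sum of squared errors (constant response, or all candidate
    values constant).
    """
    if len(table) == 0:
        raise ValueError("best_split requires at least one row")
    if candidate_vars is None:
        candidate_vars = list(table.columns)
    if len(candidate_vars) == 0:
        raise ValueError("candidate_vars must be nonempty")
    X, enc = encode_frame(table)
    _check_complete(X)
    y = np.asarray(y, dtype=np.float64)
    cand = np.sort(np.array([enc.columns.index(v) for v in candidate_vars],
                            dtype=np.int64))
    idx = np.arange(len(table), dtype=np.int64)
    var, thr, mask, red = _kernels.best_split_node(
        X, y, idx, 0, len(table), cand, enc.kinds, enc.n_levels)
    if var < 0:
        return None
    return _decision_from_arrays(enc, int(var), float(thr), int(mask),
                                 float(red))


def _grow_encoded(X, y, enc, m, n_min, rng, sample_idx=None) -> RegressionTree:
    n = len(X)
    cap = max(2 * n, 3)
    if sample_idx is None:
        sample_idx = np.arange(n, dtype=np.int64)
    var_keys = rng.random((cap, X.shape[1]))
    feature = np.empty(cap, dtype=np.int64)
    threshold = np.empty(cap, dtype=np.float64)
    cat_mask = np.empty(cap, dtype=np.int64)
    left = np.empty(cap, dtype=np.int64)
    right = np.empty(cap, dtype=np.int64)
    value = np.empty(cap, dtype=np.float64)
    node_size = np.empty(cap, dtype=np.int64)
    count = _kernels.grow_tree(X, y, enc.kinds, enc.n_levels, sample_idx,
                               m, n_min, var_keys, feature, threshold,
                               cat_mask, left, right, value, node_size)
    sl = slice(0, count)
    return RegressionTree(enc, feature[sl].copy(), threshold[sl].copy(),
                          cat_mask[sl].copy(), left[sl].copy(),
                          right[sl].copy(), value[sl].copy(),
                          node_size[sl].copy())


def grow_tree(table: pd.DataFrame, y, m=None, n_min=5, rng=None) -> RegressionTree:
    """Grow a single regression tree on a complete table.

    ``m`` candidate predictors are drawn uniformly without replacement at
    every node (``m=None`` means all predictors, i.e. deterministic CART).
    Nodes with fewer than ``n_min`` rows, or with no strictly
    error-reducing split, become leaves holding their mean response.
    """
    if len(table) == 0:
        raise ValueError("grow_tree requires at least one row")
    X, enc = encode_frame(table)
    _check_complete(X)
    y = np.asarray(y, dtype=np.float64)
    p = X.shape[1]
    if m is None:
        m = p
    if not 1 <= m <= p:
        raise ValueError(f"m must be in [1, p={p}], got {m}")
    rng = np.random.default_rng(rng)
    return _grow_encoded(X, y, enc, m, n_min, rng)


@dataclass
class Forest:
    """Bagged ensemble of regression trees; prediction is the plain average
    of the per-tree predictions."""

    trees: list
    params: ForestParams
    encoding: _Encoding
    seed: int | None = None
    response_range: tuple | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = self.encoding.encode(X)
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if np.isnan(X).any():
            raise MissingValueError(
                "prediction inputs contain missing values; impute first")
        out = np.zeros(len(X))
        enc = self.encoding
        for t in self.trees:
            _kernels.accumulate_tree_prediction(
                X, enc.kinds, t.feature, t.threshold, t.cat_mask,
                t.left, t.right, t.value, out)
        return out / self.n_trees

    def to_json(self, path=None) -> str:
        doc = {
            "format": "cbfsurrogate-forest/1",
            "params": {"n_trees": self.params.n_trees, "m": self.params.m,
                       "n_min": self.params.n_min,
                       "bootstrap": self.params.bootstrap},
            "seed": self.seed,
            "encoding": self.encoding.to_dict(),
            "response_range": list(self.response_range)
            if self.response_range else None,
            "trees": [t.to_dict() for t in self.trees],
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "Forest":
        text = text_or_path
        if "\n" not in text and text.strip()[:1] != "{":
            with open(text_or_path) as fh:
                text = fh.read()
        doc = json.loads(text)
        if doc.get("format") != "cbfsurrogate-forest/1":
            raise ValueError("not a cbfsurrogate forest document")
        enc = _Encoding.from_dict(doc["encoding"])
        params = ForestParams(**doc["params"])
        trees = [RegressionTree.from_dict(d, enc) for d in doc["trees"]]
        rr = doc.get("response_range")
        return cls(trees, params, enc, doc.get("seed"),
                   tuple(rr) if rr else None)


def fit_forest_encoded(X, y, enc, params: ForestParams, seed) -> Forest:
    """Fit a forest on a pre-encoded design matrix (fast path used by the
    cross-validation loops, which encode the table once)."""
    params.validate(X.shape[1])
    _check_complete(X)
    n = len(X)
    if n < 1:
        raise ValueError("training table is empty")
    y = np.asarray(y, dtype=np.float64)
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    streams = ss.spawn(params.n_trees)
    trees = []
    for child in streams:
        rng = np.random.default_rng(child)
        if params.bootstrap:
            sample = rng.integers(0, n, size=n).astype(np.int64)
        else:
            sample = np.arange(n, dtype=np.int64)
        trees.append(_grow_encoded(X, y, enc, params.m, params.n_min, rng,
                                   sample_idx=sample))
    return Forest(trees, params, enc, seed,
                  (float(np.min(y)), float(np.max(y))))


def fit_forest(table: pd.DataFrame, y, params: ForestParams | None = None,
               seed=0) -> Forest:
    """Fit a random forest on a complete mixed-type table.

    Each tree is grown on an independent bootstrap resample of size N, with
    per-tree random streams spawned from the master seed so fits are
    reproducible and independent of evaluation order.
    """
    if params is None:
        params = ForestParams()
    X, enc = encode_frame(table)
    if isinstance(y, str):
        raise TypeError("pass the response as a vector, not a column name")
    return fit_forest_encoded(X, np.asarray(y, dtype=np.float64), enc,
                              params, seed)


def predict_forest(forest: Forest, x) -> float | np.ndarray:
    """Average of the per-tree predictions at ``x``.

    A single row (Series or 1-D vector) yields a scalar; a frame or matrix
    yields a vector of predictions.
    """
    if isinstance(x, pd.Series):
        return float(forest.predict(x.to_frame().T)[0])
    if not isinstance(x, pd.DataFrame) and np.ndim(x) == 1:
        return float(forest.predict(np.asarray(x, dtype=np.float64)[None, :])[0])
    return forest.predict(x)
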