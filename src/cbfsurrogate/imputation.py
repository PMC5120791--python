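"""Iterative random-forest imputation of a mixed-type data matrix.

The N x (p+1) matrix xi (predictors plus response) is imputed column by
column: missing cells are first filled by column mean (numeric) or mode
(categorical); then, for each column s with missing entries, a forest is
fitted on the rows where xi^(s) is observed — predictors are all the other
columns at their current values, response is the observed part of xi^(s) —
and applied to the remaining rows to refresh the missing part.  Sweeps over
the columns repeat until the matrix stops changing.

Convergence is monitored through two change statistics over the originally
missing cells: the relative squared numeric change
sum (curr - prev)^2 / sum curr^2 and the fraction of categorical cells
that switched level.  The loop stops when both fall below tolerance, when
the numeric statistic first increases (the established stopping rule for
this scheme — the previous sweep's matrix is returned), or at the
iteration cap.  Columns are visited in ascending order of missing count so
the best-observed columns stabilise first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import ForestParams, _Encoding, encode_frame, fit_forest_encoded

__all__ = [
    "DataMatrix",
    "ImputationReport",
    "FullyMissingColumnError",
    "mean_mode_initialize",
    "imputation_delta",
    "impute",
]

DEFAULT_IMPUTATION_PARAMS = ForestParams(n_trees=100, m=3, n_min=5)


class FullyMissingColumnError(ValueError):
    """A column has no observed values to learn from."""


@dataclass
class DataMatrix:
    """A mixed-type data matrix with its missingness mask.

    ``frame`` holds the current cell values; ``missing`` is a boolean frame
    (True = the cell was missing in the original data) kept separately so
    the original missingness stays recoverable after filling.
    """

    frame: pd.DataFrame
    missing: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DataMatrix":
        return cls(df.copy(), df.isna())

    @property
    def n_missing(self) -> int:
        return int(self.missing.to_numpy().sum())

    def i_mis(self, column) -> np.ndarray:
        """Positional indices of originally missing cells in ``column``."""
        return np.flatnonzero(self.missing[column].to_numpy())

    def i_obs(self, column) -> np.ndarray:
        return np.flatnonzero(~self.missing[column].to_numpy())

    def is_numeric(self, column) -> bool:
        col = self.frame[column]
        return (pd.api.types.is_numeric_dtype(col)
                and not pd.api.types.is_bool_dtype(col))

    def copy(self) -> "DataMatrix":
        return DataMatrix(self.frame.copy(), self.missing.copy())


def _as_matrix(m) -> DataMatrix:
    return m if isinstance(m, DataMatrix) else DataMatrix.from_frame(m)


def _check_columns(dm: DataMatrix, columns) -> None:
    for c in columns:
        if len(dm.i_obs(c)) == 0:
            raise FullyMissingColumnError(
                f"column {c!r} has no observed values")


def mean_mode_initialize(matrix) -> DataMatrix:
    """Fill missing cells with the column mean (numeric) or mode
    (categorical; ties broken toward the smaller level).  Observed cells
    are untouched and the mask is preserved."""
    dm = _as_matrix(matrix).copy()
    _check_columns(dm, dm.frame.columns)
    for c in dm.frame.columns:
        mis = dm.i_mis(c)
        if len(mis) == 0:
            continue
        obs_vals = dm.frame[c].iloc[dm.i_obs(c)]
        if dm.is_numeric(c):
            fill = float(obs_vals.mean())
        else:
            counts = obs_vals.value_counts()
            top = counts.max()
            fill = sorted(str(k) for k, v in counts.items() if v == top)[0]
            # keep the original (non-string) level object if applicable
            fill = next(k for k in counts.index if str(k) == fill)
        col = dm.frame[c].copy()
        col.iloc[mis] = fill
        dm.frame[c] = col
    return dm


def imputation_delta(prev, curr, mask: pd.DataFrame) -> tuple[float, float]:
    """Change between two filled matrices over the originally missing cells.

    Numeric change: sum over missing numeric cells of (curr - prev)^2
    divided by sum of curr^2 (0 when there is nothing to compare, or when
    the denominator vanishes).  Categorical change: fraction of missing
    categorical cells whose level changed.
    """
    prev_f = prev.frame if isinstance(prev, DataMatrix) else prev
    curr_f = curr.frame if isinstance(curr, DataMatrix) else curr
    if prev_f.shape != curr_f.shape or list(prev_f.columns) != list(curr_f.columns):
        raise ValueError("imputation_delta requires matrices of identical "
                         "shape and columns")
    num_num = 0.0
    num_den = 0.0
    cat_changed = 0
    cat_total = 0
    tmp = _as_matrix(curr_f)
    for c in curr_f.columns:
        mis = np.flatnonzero(mask[c].to_numpy())
        if len(mis) == 0:
            continue
        a = prev_f[c].iloc[mis].to_numpy()
        b = curr_f[c].iloc[mis].to_numpy()
        if tmp.is_numeric(c):
            a = a.astype(float)
            b = b.astype(float)
            num_num += float(np.sum((b - a) ** 2))
            num_den += float(np.sum(b ** 2))
        else:
            cat_total += len(mis)
            cat_changed += int(np.sum(a != b))
    num = num_num / num_den if num_den > 0 else 0.0
    cat = cat_changed / cat_total if cat_total else 0.0
    return num, cat


@dataclass
class ImputationReport:
    """Trace of one imputation run: per-sweep (numeric, categorical) change
    statistics, whether the convergence rule (tolerance or first numeric
    increase) stopped the loop, and why it stopped."""

    iterations: int
    trace: list = field(default_factory=list)
    converged: bool = False
    reason: str = ""


def _fit_predict_column(X_all, enc, target_j, obs, mis, y, params, seed):
    keep = [j for j in range(X_all.shape[1]) if j != target_j]
    cols = [enc.columns[j] for j in keep]
    sub = _Encoding(cols, enc.kinds[keep],
                    {c: enc.levels[c] for c in cols if c in enc.levels})
    Xp = np.ascontiguousarray(X_all[:, keep])
    m_eff = min(params.m, len(keep))
    p = ForestParams(n_trees=params.n_trees, m=m_eff, n_min=params.n_min,
                     bootstrap=params.bootstrap)
    forest = fit_forest_encoded(Xp[obs], y, sub, p, seed)
    return forest.predict(Xp[mis])


def impute(matrix, params: ForestParams | None = None, max_iter: int = 10,
           seed: int = 0, tol_numeric: float = 1e-4,
           tol_categorical: float = 0.0,
           exclude: tuple = ()) -> tuple[DataMatrix, ImputationReport]:
    """Iteratively impute a mixed-type matrix with random forests.

    Returns a complete :class:`DataMatrix` (original observed cells
    bit-identical, imputed categorical cells restricted to observed
    levels) and an :class:`ImputationReport`.  Non-convergence by
    ``max_iter`` is reported, not raised.  Columns named in ``exclude``
    are neither imputed nor used as predictors (use this for the response
    before cross-validation to avoid leaking it into the training rows).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if params is None:
        params = DEFAULT_IMPUTATION_PARAMS
    dm0 = _as_matrix(matrix)
    active = [c for c in dm0.frame.columns if c not in exclude]
    _check_columns(dm0, active)
    work = mean_mode_initialize(
        DataMatrix(dm0.frame[active], dm0.missing[active]))
    mask = work.missing
    targets = [c for c in active if len(work.i_mis(c)) > 0]
    targets.sort(key=lambda c: (len(work.i_mis(c)), active.index(c)))
    ss = np.random.SeedSequence(seed)
    report = ImputationReport(iterations=0)
    if not targets:
        report.iterations = 1
        report.trace.append((0.0, 0.0))
        report.converged = True
        report.reason = "tolerance"
        return _restore(dm0, work, exclude), report

    prev = work.copy()
    best = work.copy()
    prev_num = np.inf
    for it in range(1, max_iter + 1):
        X_all, enc = encode_frame(work.frame)
        for c in targets:
            j = enc.columns.index(c)
            obs = work.i_obs(c)
            mis = work.i_mis(c)
            stream = ss.spawn(1)[0]
            if work.is_numeric(c):
                pred = _fit_predict_column(X_all, enc, j, obs, mis,
                                           X_all[obs, j], params, stream)
            else:
                levels = enc.levels[c]
                if len(levels) == 1:
                    pred_codes = np.zeros(len(mis), dtype=int)
                elif len(levels) == 2:
                    ind = _fit_predict_column(X_all, enc, j, obs, mis,
                                              X_all[obs, j], params, stream)
                    pred_codes = (ind > 0.5).astype(int)
                else:
                    scores = np.empty((len(levels), len(mis)))
                    for li in range(len(levels)):
                        sub_stream = ss.spawn(1)[0]
                        scores[li] = _fit_predict_column(
                            X_all, enc, j, obs, mis,
                            (X_all[obs, j] == li).astype(float),
                            params, sub_stream)
                    pred_codes = np.argmax(scores, axis=0)
                pred = np.array([levels[k] for k in pred_codes], dtype=object)
            col = work.frame[c].copy()
            col.iloc[mis] = pred
            work.frame[c] = col
            X_all[mis, j] = (pred if work.is_numeric(c)
                             else pred_codes.astype(float))
        num, cat = imputation_delta(prev, work, mask)
        report.trace.append((num, cat))
        report.iterations = it
        if num <= tol_numeric and cat <= tol_categorical:
            report.converged = True
            report.reason = "tolerance"
            best = work.copy()
            break
        if num > prev_num:
            report.converged = True
            report.reason = "delta_increase"
            # the previous sweep's matrix is the accepted answer
            break
        prev_num = num
        best = work.copy()
        prev = work.copy()
    else:
        report.converged = False
        report.reason = "max_iter"
        best = work.copy()
    return _restore(dm0, best, exclude), report


def _restore(dm0: DataMatrix, work: DataMatrix, exclude) -> DataMatrix:
    """Re-assemble the full column set: imputed active columns plus
    untouched excluded columns, in the original order."""
    out = dm0.frame.copy()
    for c in work.frame.columns:
        out[c] = work.frame[c]
    return DataMatrix(out, dm0.missing.copy())
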