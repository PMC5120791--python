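"""Grouped leave-out cross-validation designs and correlation reporting.

Four exclusion designs probe how much MRI information about a patient the
model may use when predicting one of their CBF measurements:

* ``exp1_measurement`` — leave out only the test measurement itself
  (classical leave-one-out; other measurements of the same patient and
  even the same side remain available).
* ``exp2_patient_side`` — additionally leave out every measurement sharing
  the test row's patient *and* side (the opposite side remains).
* ``exp3_same_time`` — leave out every measurement of the same patient
  taken at the same visit (earlier/later visits remain).
* ``exp4_patient`` — leave out every measurement of the test row's patient
  (leave-one-patient-out; nothing about the patient informs the model).

For every test row a fresh forest is fitted on the design's training set
and applied to that row; the vector of predictions is compared with the
observed CBF through the Pearson correlation and its two-sided t-test
p-value.  The four training sets are nested (exp4 within exp2 and exp3,
both within exp1), and the exclusion definitions are re-asserted
exhaustively on every run so leakage cannot pass silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PREDICTORS, RESPONSE
from .trees import ForestParams, encode_frame, fit_forest_encoded

__all__ = [
    "MODES",
    "ExperimentResult",
    "build_training_indices",
    "excluded_indices",
    "run_experiment",
    "pearson_r_pvalue",
    "permutation_pvalue",
    "pooled_correlation",
    "summarize",
    "plot_predictions",
]

MODES = ("exp1_measurement", "exp2_patient_side", "exp3_same_time",
         "exp4_patient")


def excluded_indices(table: pd.DataFrame, test_row: int, mode: str) -> np.ndarray:
    """Positional indices a design withholds from training for ``test_row``
    (always includes the test row itself)."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    n = len(table)
    if not 0 <= test_row < n:
        raise IndexError(f"test_row {test_row} out of range [0, {n})")
    pid = table["patient_id"].to_numpy()
    same_patient = pid == pid[test_row]
    if mode == "exp1_measurement":
        out = np.zeros(n, dtype=bool)
        out[test_row] = True
    elif mode == "exp2_patient_side":
        side = table["side"].to_numpy()
        out = same_patient & (side == side[test_row])
        out[test_row] = True
    elif mode == "exp3_same_time":
        visit = table["visit_id"].to_numpy()
        out = same_patient & (visit == visit[test_row])
        out[test_row] = True
    else:  # exp4_patient
        out = same_patient.copy()
        out[test_row] = True
    return np.flatnonzero(out)


def build_training_indices(table: pd.DataFrame, test_row: int,
                           mode: str) -> np.ndarray:
    """Training rows for ``test_row`` under the given design: everything
    except the design's exclusion set."""
    excl = excluded_indices(table, test_row, mode)
    keep = np.ones(len(table), dtype=bool)
    keep[excl] = False
    return np.flatnonzero(keep)


@dataclass
class ExperimentResult:
    """Predictions and correlation summary of one leave-out design."""

    mode: str
    y_obs: np.ndarray
    y_pred: np.ndarray
    learning_sizes: np.ndarray
    r: float
    p: float
    params: ForestParams
    seed: int

    @property
    def learning_range(self) -> str:
        lo, hi = int(self.learning_sizes.min()), int(self.learning_sizes.max())
        return str(lo) if lo == hi else f"{lo}-{hi}"


def pearson_r_pvalue(a, b) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p-value from the
    t transform t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom.
    The p-value is reported as computed, with no reporting floor."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = len(a)
    if n < 3:
        raise ValueError("correlation needs at least 3 observations")
    da = a - a.mean()
    db = b - b.mean()
    va = float(np.dot(da, da))
    vb = float(np.dot(db, db))
    if va == 0.0 or vb == 0.0:
        raise ValueError("correlation undefined for a zero-variance input")
    r = float(np.dot(da, db) / np.sqrt(va * vb))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, min(p, 1.0)


def permutation_pvalue(a, b, n_permutations: int = 10_000,
                       seed: int = 0) -> float:
    """Two-sided permutation p-value for the Pearson correlation: the
    fraction of label permutations whose |r| meets or exceeds the
    observed |r| (add-one estimator)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    r_obs, _ = pearson_r_pvalue(a, b)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        r_perm, _ = pearson_r_pvalue(a, rng.permutation(b))
        if abs(r_perm) >= abs(r_obs):
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def _assert_no_leakage(train: np.ndarray, excl: np.ndarray, mode: str,
                       test_row: int) -> None:
    inter = np.intersect1d(train, excl)
    if inter.size:
        raise AssertionError(
            f"leakage in {mode}: training set for row {test_row} contains "
            f"excluded rows {inter.tolist()}")


def run_experiment(table: pd.DataFrame, mode: str,
                   params: ForestParams | None = None, seed: int = 0,
                   predictors=None, response: str = RESPONSE,
                   observed_response_mask: np.ndarray | None = None
                   ) -> ExperimentResult:
    """Run one leave-out design over every row of a complete table.

    For each row a forest is fitted (fresh per-row random stream spawned
    from ``seed``) on that row's training set and applied to the row; the
    result carries per-row learning-set sizes, the Pearson r between
    predicted and observed CBF, and its t-test p-value.  Rows where
    ``observed_response_mask`` is False (e.g. an imputed response) are
    excluded from both testing and training.
    """
    if params is None:
        params = ForestParams()
    if predictors is None:
        predictors = [c for c in PREDICTORS if c in table.columns]
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation")
    if observed_response_mask is not None:
        table = table.iloc[np.flatnonzero(observed_response_mask)]
        table = table.reset_index(drop=True)
        if len(table) < 3:
            raise ValueError("fewer than 3 rows with observed response")
    sub = table[predictors]
    if sub.isna().to_numpy().any() or table[response].isna().any():
        raise ValueError("table has missing values; impute first")
    X, enc = encode_frame(sub)
    y = table[response].to_numpy(dtype=float)
    n = len(table)
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(n)
    preds = np.empty(n)
    sizes = np.empty(n, dtype=int)
    for i in range(n):
        train = build_training_indices(table, i, mode)
        excl = excluded_indices(table, i, mode)
        _assert_no_leakage(train, excl, mode, i)
        if len(train) < 1:
            raise ValueError(f"empty training set for row {i} under {mode}")
        forest = fit_forest_encoded(X[train], y[train], enc, params,
                                    streams[i])
        preds[i] = forest.predict(X[i:i + 1])[0]
        sizes[i] = len(train)
    r, p = pearson_r_pvalue(preds, y)
    return ExperimentResult(mode, y, preds, sizes, r, p, params, seed)


def pooled_correlation(results) -> tuple[float, float]:
    """Pearson r and p over the pooled (prediction, observation) pairs of
    several results — e.g. a stratified rerun that fits healthy and
    diseased subjects separately and reports one correlation."""
    results = list(results)
    y = np.concatenate([res.y_obs for res in results])
    yhat = np.concatenate([res.y_pred for res in results])
    return pearson_r_pvalue(yhat, y)


def summarize(results) -> pd.DataFrame:
    """Machine-readable analogue of the study's summary table: one row per
    experiment with the learning-set size range (a single number when all
    rows share it, otherwise ``min-max``), r and p."""
    results = list(results)
    if not results:
        raise ValueError("summarize needs at least one experiment result")
    rows = []
    for res in results:
        if len(res.y_pred) == 0:
            raise ValueError("experiment result has no predictions")
        rows.append({"experiment": res.mode,
                     "learning_data": res.learning_range,
                     "r": res.r, "p": res.p})
    return pd.DataFrame(rows, columns=["experiment", "learning_data",
                                       "r", "p"])


def plot_predictions(results, path=None):
    """Scatter plots of observed vs predicted CBF, one panel per
    experiment, with the identity line for reference."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results = list(results)
    ncol = min(2, len(results))
    nrow = (len(results) + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(5 * ncol, 4.5 * nrow),
                             squeeze=False)
    for k, res in enumerate(results):
        ax = axes[k // ncol][k % ncol]
        ax.scatter(res.y_pred, res.y_obs, s=12, alpha=0.7)
        lims = [min(res.y_obs.min(), res.y_pred.min()),
                max(res.y_obs.max(), res.y_pred.max())]
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel("predicted CBF (ml/min/100g)")
        ax.set_ylabel("observed CBF (ml/min/100g)")
        ax.set_title(f"{res.mode}: r = {res.r:.2f}, p = {res.p:.2g}")
    for k in range(len(results), nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
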