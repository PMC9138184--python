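"""Scoring, statistical baselines, drop-rate sweeps and causal-recovery AUROC.

RMSE and MAE are computed only over the artificially dropped entries (the
eval mask), on the normalized 0-1 scale, pooled across attributes and
timesteps.  The statistical baselines (zero, mean, median, random, LOCF) use
per-attribute observed statistics and serve as reference points for the
learned imputer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .network import ImputationModel, impute
from .timeseries import TimeSeriesDataset, inject_missing

__all__ = [
    "rmse",
    "mae",
    "baseline_impute",
    "causal_recovery_auroc",
    "sweep",
    "BASELINE_METHODS",
]

BASELINE_METHODS = ("zero", "mean", "median", "random", "locf")


def _masked_errors(truth, imputed, eval_mask) -> np.ndarray:
    truth = np.asarray(truth, dtype=np.float64)
    imputed = np.asarray(imputed, dtype=np.float64)
    eval_mask = np.asarray(eval_mask)
    if truth.shape != imputed.shape or truth.shape != eval_mask.shape:
        raise ValueError("truth, imputed and eval_mask must share a shape")
    sel = eval_mask == 1
    if not sel.any():
        raise ValueError("eval_mask selects no entries")
    return truth[sel] - imputed[sel]


def rmse(truth, imputed, eval_mask) -> float:
    """Root mean squared error over the dropped (eval-mask) entries."""
    err = _masked_errors(truth, imputed, eval_mask)
    return float(np.sqrt(np.mean(err**2)))


def mae(truth, imputed, eval_mask) -> float:
    """Mean absolute error over the dropped (eval-mask) entries."""
    err = _masked_errors(truth, imputed, eval_mask)
    return float(np.mean(np.abs(err)))


def baseline_impute(dataset: TimeSeriesDataset, method: str,
                    seed: int | None = None) -> TimeSeriesDataset:
    """Closed-form statistical imputation: zero, mean, median, random or LOCF.

    Works on the normalized scale; ``random`` draws uniform [0, 1] values
    under ``seed``; LOCF carries the last observation forward and falls back
    to the attribute mean before the first observation.
    """
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown baseline {method!r}; choose from {BASELINE_METHODS}")
    if np.any(dataset.mask.sum(axis=0) == 0):
        raise ValueError("every attribute needs at least one observed entry")
    values = dataset.values.copy()
    missing = dataset.mask == 0
    if method == "zero":
        values[missing] = 0.0
    elif method in ("mean", "median"):
        stat = np.nanmean(values, axis=0) if method == "mean" else np.nanmedian(values, axis=0)
        values = np.where(missing, stat, values)
    elif method == "random":
        rng = np.random.default_rng(seed)
        values[missing] = rng.uniform(0.0, 1.0, size=int(missing.sum()))
    elif method == "locf":
        means = np.nanmean(values, axis=0)
        for j in range(dataset.d):
            last = means[j]
            for t in range(dataset.n):
                if dataset.mask[t, j] == 1:
                    last = values[t, j]
                else:
                    values[t, j] = last
    return TimeSeriesDataset(values, np.ones_like(dataset.mask),
                             dataset.timestamps.copy(), list(dataset.attribute_names))


def causal_recovery_auroc(A_est: np.ndarray, A_true: np.ndarray) -> float:
    """AUROC of estimated off-diagonal edge scores against the true edge set."""
    A_est = np.asarray(A_est, dtype=np.float64)
    A_true = np.asarray(A_true)
    if A_est.shape != A_true.shape or A_est.ndim != 2:
        raise ValueError("adjacency matrices must share a square shape")
    off = ~np.eye(A_est.shape[0], dtype=bool)
    labels = (A_true[off] != 0).astype(int)
    if labels.min() == labels.max():
        raise ValueError("true off-diagonal edge set is degenerate (all 0 or all 1)")
    return float(roc_auc_score(labels, A_est[off]))


def _method_imputer(method, model: ImputationModel | None):
    if callable(method):
        return method
    if method == "model":
        if model is None:
            raise ValueError("no trained model supplied for method 'model'")
        return lambda ds, seed: impute(model, ds, normalized=True)
    return lambda ds, seed: baseline_impute(ds, method, seed=seed)


def sweep(benchmark, methods, p_list, seeds,
          model: ImputationModel | None = None) -> pd.DataFrame:
    """Missing-rate sweep: corrupt the test split at each rate, impute, score.

    ``methods`` is a list of baseline names, the string ``"model"`` (uses the
    supplied trained model) or callables ``(dataset, seed) -> completed
    dataset``.  Returns a tidy report with one row per method and missing
    rate: RMSE/MAE averaged over seeds, the number of scored entries, and the
    seeds used.
    """
    if len(seeds) < 1:
        raise ValueError("need at least one seed")
    if any(not 0 < p < 1 for p in p_list):
        raise ValueError("all missing rates must be in (0, 1)")
    truth = benchmark.test_truth
    rows = []
    for p in p_list:
        for method in methods:
            name = method if isinstance(method, str) else getattr(
                method, "__name__", "custom")
            imputer = _method_imputer(method, model)
            r_vals, m_vals, n_scored = [], [], 0
            for seed in seeds:
                corrupted, eval_mask = inject_missing(truth, p, seed)
                completed = imputer(corrupted, seed)
                r_vals.append(rmse(truth.values, completed.values, eval_mask))
                m_vals.append(mae(truth.values, completed.values, eval_mask))
                n_scored = int(eval_mask.sum())
            rows.append({"method": name, "missing_rate": p,
                         "rmse": float(np.mean(r_vals)), "mae": float(np.mean(m_vals)),
                         "n_scored": n_scored,
                         "seeds": ";".join(str(s) for s in seeds)})
    return pd.DataFrame(rows)
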