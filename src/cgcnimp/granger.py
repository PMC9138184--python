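"""Neural Granger causality with group-sparse input weights.

One single-layer LSTM predictor per target attribute ``j`` forecasts
``x[t, j]`` one step ahead from all attributes at ``t-1`` and earlier.  The
stacked gate input matrix ``W^(j)`` (forget/input/output/candidate rows, shape
``4H x d``) is penalized with a group lasso across its columns: the column
group of input attribute ``i`` is either shrunk to exactly zero (no Granger
edge ``i -> j``) or kept.  The directed causal-strength matrix is

    A[i, j] = || column group i of W^(j) ||_F^2

Fitting uses Adam on the smooth masked prediction error plus a proximal group
soft-threshold step each iteration, which produces exact zero groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor, as_tensor
from .timeseries import TimeSeriesDataset, segment

__all__ = [
    "GrangerConfig",
    "GrangerModel",
    "lstm_cell",
    "predict_series",
    "group_penalty",
    "granger_loss",
    "extract_adjacency",
    "fit_granger",
    "write_adjacency",
    "read_adjacency",
]


@dataclass
class GrangerConfig:
    """Hyperparameters of the causal-discovery submodel.

    lam is the group-lasso weight on a per-residual scale (the fitted
    objective divides the squared-error sum by the number of residual terms).
    """

    hidden_size: int = 16
    lam: float = 0.1
    lr: float = 0.02
    epochs: int = 250
    window_length: int = 48
    seed: int = 0


class GrangerModel:
    """d component-wise LSTM predictors; one parameter set per target."""

    def __init__(self, d: int, hidden_size: int, seed: int = 0,
                 attribute_names: list[str] | None = None):
        self.d = d
        self.hidden_size = hidden_size
        self.attribute_names = attribute_names or [f"attr_{j}" for j in range(d)]
        rng = np.random.default_rng(seed)
        H = hidden_size
        self.targets = []
        for _ in range(d):
            # small input-weight init so the group threshold can prune early
            scale = 0.3 / np.sqrt(d)
            self.targets.append({
                "W": Tensor(rng.normal(0, scale, (4 * H, d)), requires_grad=True),
                "U": Tensor(rng.normal(0, 1.0 / np.sqrt(H), (4 * H, H)), requires_grad=True),
                "b": Tensor(np.zeros(4 * H), requires_grad=True),
                "w_out": Tensor(rng.normal(0, 1.0 / np.sqrt(H), (1, H)), requires_grad=True),
                "b_out": Tensor(np.zeros(1), requires_grad=True),
            })

    def parameters(self) -> list[Tensor]:
        return [p for t in self.targets for p in t.values()]

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for j, t in enumerate(self.targets):
            for k, v in t.items():
                out[f"granger_{j}_{k}"] = v.data
        return out

    def load_state_arrays(self, arrays: dict) -> None:
        for j, t in enumerate(self.targets):
            for k in t:
                t[k].data = np.asarray(arrays[f"granger_{j}_{k}"], dtype=np.float64)


def _lstm_cell_t(x_t: Tensor, h_prev: Tensor, c_prev: Tensor, params: dict
                 ) -> tuple[Tensor, Tensor]:
    """One LSTM step on tensors; gate row order f, i, o, c in W, U, b."""
    H = params["U"].shape[1]
    z = x_t @ params["W"].T + h_prev @ params["U"].T + params["b"]
    f = z[..., 0:H].sigmoid()
    i = z[..., H:2 * H].sigmoid()
    o = z[..., 2 * H:3 * H].sigmoid()
    g = z[..., 3 * H:4 * H].tanh()
    c_t = f * c_prev + i * g
    h_t = o * c_t.tanh()
    return h_t, c_t


def lstm_cell(x_t, h_prev, c_prev, params) -> tuple[np.ndarray, np.ndarray]:
    """Standard LSTM cell update (sigmoid gates, tanh candidate).

    ``params`` holds the stacked gate matrices ``W`` (4H x d), ``U`` (4H x H)
    and bias ``b`` (4H), rows ordered forget/input/output/candidate.
    """
    x_t = np.atleast_1d(np.asarray(x_t, dtype=np.float64))
    h_prev = np.asarray(h_prev, dtype=np.float64)
    c_prev = np.asarray(c_prev, dtype=np.float64)
    p = {k: as_tensor(v) for k, v in params.items()}
    if p["W"].shape[0] != 4 * p["U"].shape[1] or p["W"].shape[1] != x_t.shape[-1]:
        raise ValueError("parameter shapes inconsistent with input/hidden size")
    h, c = _lstm_cell_t(Tensor(x_t), Tensor(h_prev), Tensor(c_prev), p)
    return h.data, c.data


def _predict_t(params: dict, X: Tensor) -> Tensor:
    """One-step-ahead predictions for one target over a (B, T, d) batch.

    Returns predictions of shape (B, T-1): entry t-1 predicts timestep t from
    inputs strictly before t.
    """
    B, T, d = X.shape
    H = params["U"].shape[1]
    h = Tensor(np.zeros((B, H)))
    c = Tensor(np.zeros((B, H)))
    preds = []
    for t in range(T - 1):
        h, c = _lstm_cell_t(X[:, t, :], h, c, params)
        preds.append(h @ params["w_out"].T + params["b_out"])
    from .autodiff import concat
    return concat(preds, axis=-1)


def predict_series(model: GrangerModel, j: int, X_past: np.ndarray) -> np.ndarray:
    """Predict attribute ``j`` one step ahead along a fully-valued window.

    Returns a length ``T-1`` vector: element ``t-1`` is the prediction of
    ``x[t, j]`` from ``x[<t]``.
    """
    X_past = np.asarray(X_past, dtype=np.float64)
    if X_past.ndim != 2 or X_past.shape[0] < 2:
        raise ValueError("need an n x d window with n >= 2")
    out = _predict_t(model.targets[j], Tensor(X_past[None]))
    return out.data[0]


def group_penalty(W_stacked):
    """Group-lasso penalty: sum over input attributes of the column-group norm.

    Returns a float for arrays; stays symbolic (differentiable) for tensors
    that participate in a computation graph.
    """
    if isinstance(W_stacked, Tensor) and (W_stacked.requires_grad or W_stacked._parents):
        return (((W_stacked**2).sum(axis=0)) ** 0.5).sum()
    W = W_stacked.data if isinstance(W_stacked, Tensor) else np.asarray(W_stacked, float)
    return float(np.sqrt((W**2).sum(axis=0)).sum())


def extract_adjacency(model: GrangerModel) -> np.ndarray:
    """Directed causal-strength matrix: A[i, j] = ||W^(j) column group i||_F^2."""
    A = np.zeros((model.d, model.d))
    for j, t in enumerate(model.targets):
        A[:, j] = (t["W"].data ** 2).sum(axis=0)
    return A


def _adjacency_t(model: GrangerModel) -> Tensor:
    """Adjacency as a tensor so gradients can flow into the Granger weights."""
    from .autodiff import concat
    cols = [(t["W"] ** 2).sum(axis=0).reshape(model.d, 1) for t in model.targets]
    return concat(cols, axis=1)


def granger_loss(model: GrangerModel, window: TimeSeriesDataset, lam: float) -> float:
    """Masked one-step squared error summed over targets, plus the group penalty.

    Only timesteps where the target attribute is observed contribute a
    residual; inputs are the zero-filled window values.
    """
    if lam < 0:
        raise ValueError("penalty weight lam must be >= 0")
    X = window.filled(0.0)
    total = 0.0
    for j in range(model.d):
        pred = predict_series(model, j, X)
        m = window.mask[1:, j].astype(bool)
        resid = X[1:, j][m] - pred[m]
        total += float((resid**2).sum())
        total += lam * group_penalty(model.targets[j]["W"].data)
    return total


def _prox_group(W: np.ndarray, thresh: float) -> np.ndarray:
    """Column-group soft threshold: g <- max(0, 1 - thresh/||g||) g."""
    norms = np.sqrt((W**2).sum(axis=0))
    scale = np.where(norms > thresh, 1.0 - thresh / np.maximum(norms, 1e-300), 0.0)
    return W * scale


def _stack_windows(dataset: TimeSeriesDataset, window_length: int
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Zero-filled values, mask and lag matrices stacked as (B, T, d) batches.

    Windows shorter than the modal length (the kept remainder) are excluded
    from the training batch so shapes are rectangular.
    """
    wins = segment(dataset, window_length)
    T = max(w.n for w in wins)
    wins = [w for w in wins if w.n == T]
    X = np.stack([w.filled(0.0) for w in wins])
    M = np.stack([w.mask for w in wins]).astype(np.float64)
    D = np.stack([w.time_lag() for w in wins])
    return X, M, D


def fit_granger(dataset: TimeSeriesDataset, config: GrangerConfig) -> tuple[GrangerModel, list]:
    """Fit the component-wise predictors by Adam plus proximal group thresholding.

    The smooth part of the objective is the masked squared one-step error
    averaged over residual terms; after each Adam step every column group of
    each W^(j) is soft-thresholded with threshold ``lr * lam``, giving exact
    zeros for pruned inputs.  Deterministic for a fixed seed.

    Returns the model and a per-epoch history of dicts with keys
    ``objective`` (residual + lam * penalty), ``residual`` and ``penalty``.
    The penalty can drift upward as true parent groups grow, so the
    ``residual`` entry is the one that decreases with fitting.
    """
    model = GrangerModel(dataset.d, config.hidden_size, seed=config.seed,
                         attribute_names=list(dataset.attribute_names))
    X, M, _ = _stack_windows(dataset, config.window_length)
    Xt = Tensor(X)
    history = []
    opts = [Adam(t.values(), lr=config.lr) for t in model.targets]
    for epoch in range(config.epochs):
        epoch_resid = 0.0
        epoch_pen = 0.0
        for j, (params, opt) in enumerate(zip(model.targets, opts)):
            pred = _predict_t(params, Xt)  # (B, T-1)
            m = Tensor(M[:, 1:, j])
            n_terms = max(M[:, 1:, j].sum(), 1.0)
            resid = (Tensor(X[:, 1:, j]) - pred) * m
            loss = (resid**2).sum() * (1.0 / n_terms)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite causality loss at epoch {epoch}, target {j}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            params["W"].data = _prox_group(params["W"].data, config.lr * config.lam)
            epoch_resid += loss.item()
            epoch_pen += group_penalty(params["W"].data)
        history.append({"objective": epoch_resid + config.lam * epoch_pen,
                        "residual": epoch_resid, "penalty": epoch_pen})
    return model, history


def write_adjacency(A: np.ndarray, attribute_names: list[str], path) -> None:
    pd.DataFrame(A, index=attribute_names, columns=attribute_names).to_csv(path)


def read_adjacency(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=np.float64), list(df.columns)
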