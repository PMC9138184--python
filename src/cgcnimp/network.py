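"""The imputation network: causal GCN, time-decay LSTM, attention, readout.

Forward pass over one window of length T with d attributes:

1. The causal adjacency A (from the Granger submodel) is rescaled to max
   entry 1, given self-loops and symmetrically degree-normalized; each
   timestep's attribute vector is mixed through this matrix and passed through
   a shared feature transform (the GCN layer).
2. A decay vector ``alpha_t = 1 / exp(max(0, W_a @ delta_t + b_a))`` in (0, 1]
   shrinks the recurrent hidden state according to how stale each attribute's
   last observation is; an LSTM whose gates read ``[alpha_t * h_{t-1}; H_G_t]``
   produces hidden states H_L.  Only the hidden state is decayed, not the cell
   state.
3. Full pairwise temporal attention re-weights the hidden states (each output
   row is a convex combination of all T hidden states), and a linear head maps
   the attended states back to d attribute values.

Imputation keeps observed entries bit-identical and fills absent ones with the
reconstruction, then denormalizes through the stored scaler.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concat
from .timeseries import Scaler, TimeSeriesDataset, invert_scaler, segment

__all__ = [
    "ImputationConfig",
    "ImputationModel",
    "normalized_adjacency",
    "gcn_forward",
    "decay_vector",
    "decay_lstm_step",
    "attention",
    "reconstruct",
    "impute",
]

_ACTIVATIONS = {
    "relu": lambda t: t.relu(),
    "tanh": lambda t: t.tanh(),
    "identity": lambda t: t,
}


def _normalized_adjacency_t(A: Tensor) -> Tensor:
    d = A.shape[0]
    amax = float(A.data.max())
    if amax > 0:
        A = A * (1.0 / amax)  # rescale treated as a constant of the graph
    A_tilde = A + Tensor(np.eye(d))
    deg = A_tilde.sum(axis=1, keepdims=True)  # row sums of the self-looped matrix
    dinv = deg**-0.5
    return A_tilde * dinv * dinv.T


def normalized_adjacency(A) -> np.ndarray:
    """Self-looped, symmetrically degree-normalized adjacency.

    A is first rescaled to maximum entry 1 (keeping its strengths comparable
    to the unit self-loop), then D^{-1/2} (A + I) D^{-1/2} with D the diagonal
    of row sums.
    """
    arr = A.data if isinstance(A, Tensor) else np.asarray(A, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(arr < 0):
        raise ValueError("adjacency entries must be nonnegative")
    return _normalized_adjacency_t(as_tensor(A)).data


def _gcn_forward_t(X: Tensor, A_hat: Tensor, theta: Tensor, activation: str) -> Tensor:
    mixed = X @ A_hat.T  # (..., T, d): node mixing per timestep
    d_gcn = theta.shape[-1]
    expanded = mixed.reshape(*mixed.shape, 1) @ theta  # shared per-node transform
    out = _ACTIVATIONS[activation](expanded)
    return out.reshape(*mixed.shape[:-1], mixed.shape[-1] * d_gcn)


def gcn_forward(X_window, A_hat, theta, activation: str = "relu") -> np.ndarray:
    """Graph convolution over attributes, applied independently per timestep.

    Each timestep's d-vector is mixed by the normalized adjacency; each node's
    mixed scalar is then expanded by the shared 1 x d_gcn feature transform
    ``theta`` and passed through the activation.  Output is node-major
    flattened, shape (T, d * d_gcn); with the default d_gcn = 1 it is (T, d).
    """
    X = np.asarray(X_window, dtype=np.float64)
    A = np.asarray(A_hat.data if isinstance(A_hat, Tensor) else A_hat, dtype=np.float64)
    if X.shape[-1] != A.shape[0]:
        raise ValueError("attribute count of window and adjacency differ")
    th = np.atleast_2d(np.asarray(theta, dtype=np.float64))
    return _gcn_forward_t(Tensor(X), Tensor(A), Tensor(th), activation).data


def _decay_vector_t(delta_t: Tensor, W_a: Tensor, b_a: Tensor) -> Tensor:
    z = (delta_t @ W_a.T + b_a).relu()
    return (-z).exp()  # 1 / exp(max(0, .)), always in (0, 1]


def decay_vector(delta_t, W_a, b_a) -> np.ndarray:
    """Time-decay factors ``1 / exp(max(0, W_a @ delta_t + b_a))`` in (0, 1]."""
    return _decay_vector_t(as_tensor(np.atleast_1d(delta_t)), as_tensor(W_a),
                           as_tensor(np.atleast_1d(b_a))).data


def _decay_lstm_step_t(h_prev: Tensor, s_prev: Tensor, hg_t: Tensor, alpha_t: Tensor,
                       params: dict) -> tuple[Tensor, Tensor]:
    """Gate order i, f, s(candidate), o in the stacked matrix/bias."""
    H = h_prev.shape[-1]
    h_dec = alpha_t * h_prev  # only the hidden state decays
    z = concat([h_dec, hg_t], axis=-1) @ params["W"].T + params["b"]
    i = z[..., 0:H].sigmoid()
    f = z[..., H:2 * H].sigmoid()
    g = z[..., 2 * H:3 * H].tanh()
    o = z[..., 3 * H:4 * H].sigmoid()
    s_t = f * s_prev + i * g
    h_t = o * s_t.tanh()
    return h_t, s_t


def decay_lstm_step(h_prev, s_prev, hg_t, alpha_t, params
                    ) -> tuple[np.ndarray, np.ndarray]:
    """One time-decay LSTM step.

    The hidden state is first multiplied elementwise by the decay vector; all
    gates then read the concatenation of the decayed hidden state and the GCN
    features of the current timestep.  The cell state is not decayed.
    """
    h_prev = np.asarray(h_prev, dtype=np.float64)
    p = {k: as_tensor(v) for k, v in params.items()}
    H = h_prev.shape[-1]
    if p["W"].shape[0] != 4 * H:
        raise ValueError("stacked gate matrix must have 4H rows")
    h, s = _decay_lstm_step_t(Tensor(h_prev), as_tensor(s_prev), as_tensor(hg_t),
                              as_tensor(alpha_t), p)
    return h.data, s.data


def _attention_t(H_L: Tensor, w_attn: Tensor) -> tuple[Tensor, Tensor]:
    T = H_L.shape[-2]
    H = H_L.shape[-1]
    u = H_L @ w_attn[:H].reshape(H, 1)  # contribution of the first slot h_i
    v = H_L @ w_attn[H:].reshape(H, 1)  # contribution of the second slot h_j
    lead = H_L.shape[:-2]
    scores = (u.reshape(*lead, T, 1) + v.reshape(*lead, 1, T)).tanh()
    e = scores.exp()  # e[..., i, j] = exp(tanh(w . [h_i | h_j]))
    norm = e.sum(axis=-2, keepdims=True)  # normalize over i for each j
    atten = (e / norm).swapaxes(-1, -2)  # row j holds beta_{., j}: sums to 1
    return atten, atten @ H_L


def attention(H_L, w_attn) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise temporal attention.

    Scores ``exp(tanh(w . [h_i | h_j]))`` are normalized over i for each j;
    the resulting T x T matrix has rows summing to 1 and re-weights the hidden
    states: ``H' = Atten @ H_L``.
    """
    H_L = np.asarray(H_L, dtype=np.float64)
    if H_L.ndim < 2 or H_L.shape[-2] == 0:
        raise ValueError("need at least one hidden state")
    atten, hp = _attention_t(Tensor(H_L), as_tensor(w_attn))
    return atten.data, hp.data


def reconstruct(H_prime, W_out, b_out) -> np.ndarray:
    """Linear readout: ``x_hat[t] = W_out @ H'[t] + b_out``."""
    H_prime = np.asarray(H_prime, dtype=np.float64)
    return H_prime @ np.asarray(W_out, dtype=np.float64).T + np.asarray(b_out, float)


@dataclass
class ImputationConfig:
    hidden_size: int = 64
    d_gcn: int = 1
    activation: str = "relu"
    window_length: int = 48
    seed: int = 0


class ImputationModel:
    """Parameters of the GCN + decay-LSTM + attention imputer.

    Carries the adjacency it was trained with and the scaler of its training
    data so ``impute`` can run on raw-scale inputs end to end.
    """

    def __init__(self, d: int, config: ImputationConfig,
                 adjacency: np.ndarray | None = None,
                 scaler: Scaler | None = None,
                 attribute_names: list[str] | None = None):
        self.d = d
        self.config = config
        self.adjacency = np.zeros((d, d)) if adjacency is None else np.asarray(adjacency)
        self.scaler = scaler
        self.attribute_names = attribute_names or [f"attr_{j}" for j in range(d)]
        H = config.hidden_size
        dg = d * config.d_gcn
        rng = np.random.default_rng(config.seed)
        self.params = {
            "theta": Tensor(np.ones((1, config.d_gcn)), requires_grad=True),
            "W_alpha": Tensor(np.zeros((H, d)), requires_grad=True),
            "b_alpha": Tensor(np.zeros(H), requires_grad=True),
            "W": Tensor(rng.normal(0, 1.0 / np.sqrt(H + dg), (4 * H, H + dg)),
                        requires_grad=True),
            "b": Tensor(np.zeros(4 * H), requires_grad=True),
            "w_attn": Tensor(rng.normal(0, 0.1, 2 * H), requires_grad=True),
            "W_out": Tensor(rng.normal(0, 1.0 / np.sqrt(H), (d, H)), requires_grad=True),
            "b_out": Tensor(np.zeros(d), requires_grad=True),
        }

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    # -- forward --------------------------------------------------------------

    def _forward_t(self, X: Tensor, delta: np.ndarray, A: Tensor) -> Tensor:
        """Reconstruction x_hat for a (B, T, d) zero-filled batch."""
        B, T, d = X.shape
        H = self.config.hidden_size
        A_hat = _normalized_adjacency_t(A)
        hg = _gcn_forward_t(X, A_hat, self.params["theta"], self.config.activation)
        h = Tensor(np.zeros((B, H)))
        s = Tensor(np.zeros((B, H)))
        hiddens = []
        for t in range(T):
            alpha = _decay_vector_t(Tensor(delta[:, t, :]), self.params["W_alpha"],
                                    self.params["b_alpha"])
            h, s = _decay_lstm_step_t(h, s, hg[:, t, :], alpha, self.params)
            hiddens.append(h.reshape(B, 1, H))
        H_L = concat(hiddens, axis=1)
        _, H_prime = _attention_t(H_L, self.params["w_attn"])
        return H_prime @ self.params["W_out"].T + self.params["b_out"]

    def forward(self, X_filled: np.ndarray, delta: np.ndarray) -> np.ndarray:
        """Reconstruct a single (T, d) zero-filled normalized window."""
        out = self._forward_t(Tensor(np.asarray(X_filled)[None]),
                              np.asarray(delta)[None], Tensor(self.adjacency))
        return out.data[0]

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        """Single-archive serialization: npz parameter arrays plus a JSON manifest."""
        manifest = {
            "d": self.d,
            "attribute_names": self.attribute_names,
            "config": self.config.__dict__,
            "scaler": None if self.scaler is None else {
                "mins": self.scaler.mins.tolist(), "maxs": self.scaler.maxs.tolist()},
        }
        arrays = {k: v.data for k, v in self.params.items()}
        arrays["adjacency"] = self.adjacency
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("manifest.json", json.dumps(manifest))
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "ImputationModel":
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            arrays = np.load(io.BytesIO(zf.read("params.npz")))
            scaler = None
            if manifest["scaler"] is not None:
                scaler = Scaler(np.asarray(manifest["scaler"]["mins"]),
                                np.asarray(manifest["scaler"]["maxs"]))
            model = cls(manifest["d"], ImputationConfig(**manifest["config"]),
                        adjacency=arrays["adjacency"], scaler=scaler,
                        attribute_names=manifest["attribute_names"])
            for k in model.params:
                model.params[k].data = arrays[k]
        return model


def impute(model: ImputationModel, dataset: TimeSeriesDataset,
           adjacency: np.ndarray | None = None,
           normalized: bool = False) -> TimeSeriesDataset:
    """Fill every absent entry of ``dataset`` with the model's reconstruction.

    Observed entries are returned bit-identical.  Unless ``normalized`` is
    true the input is on the raw scale and is normalized through the model's
    stored scaler before the forward pass (and the output denormalized).
    Windows follow the model's training window length; a short tail is covered
    by an overlapping final window.
    """
    if dataset.d != model.d:
        raise ValueError(f"model expects {model.d} attributes, got {dataset.d}")
    A = model.adjacency if adjacency is None else np.asarray(adjacency)
    work = dataset
    if not normalized:
        if model.scaler is None:
            raise ValueError("model has no scaler; pass normalized=True")
        from .timeseries import apply_scaler
        work = apply_scaler(dataset, model.scaler)
    L = model.config.window_length
    recon = np.empty_like(work.values)
    spans = [(s, min(s + L, work.n)) for s in range(0, work.n, L)]
    # merge a short tail into an overlapping window ending at n
    covered = [(a, b) for a, b in spans if b - a >= 2]
    tail = work.n - (covered[-1][1] if covered else 0)
    if tail > 0:
        covered.append((max(0, work.n - max(L, 2)), work.n))
    for a, b in covered:
        win = TimeSeriesDataset(work.values[a:b], work.mask[a:b],
                                work.timestamps[a:b], list(work.attribute_names))
        recon[a:b] = model.forward(win.filled(0.0), win.time_lag())
    out_values = np.where(work.mask == 1, work.values, recon)
    completed = TimeSeriesDataset(out_values, np.ones_like(work.mask),
                                  work.timestamps.copy(), list(work.attribute_names))
    if not normalized:
        completed = invert_scaler(completed, model.scaler)
        # keep raw observed entries bit-identical despite the scale round trip
        vals = completed.values.copy()
        vals[dataset.mask == 1] = dataset.values[dataset.mask == 1]
        completed = TimeSeriesDataset(vals, np.ones_like(work.mask),
                                      work.timestamps.copy(), list(work.attribute_names))
    return completed
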