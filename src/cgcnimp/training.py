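"""Multi-task objective and the end-to-end joint optimization loop.

The total objective combines three components:

* the causal-discovery loss (masked one-step prediction error of the
  component-wise Granger LSTMs plus their group-lasso penalty),
* the masked reconstruction loss (squared error on observed entries only),
* a total-variation term on the reconstruction, which smooths noise while
  preserving jumps.

``total_loss`` forms the weighted sum ``w_ng * l_ng + w_rec * l_rec +
w_tv * l_tv``; setting a weight to zero ablates that component.  Inside the
training loop each component is put on a per-entry (mean) scale before
weighting so the three terms are commensurate regardless of series length;
this is a pure rescaling of the objective (equivalently of the weights and of
the group-lasso strength).

The adjacency fed to the GCN is recomputed from the current Granger weights
every step; with ``joint_causality`` on, reconstruction gradients flow back
into the causal weights, otherwise the adjacency is detached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Tensor, as_tensor
from .granger import (GrangerConfig, GrangerModel, _adjacency_t, _predict_t,
                      _prox_group, group_penalty, fit_granger)
from .network import ImputationConfig, ImputationModel
from .timeseries import TimeSeriesDataset, inject_missing
from .granger import _stack_windows

__all__ = [
    "TrainingConfig",
    "masked_loss",
    "tv_loss",
    "total_loss",
    "train",
    "train_with_dropout_protocol",
]


@dataclass
class TrainingConfig:
    """Weights and optimizer settings of the joint objective.

    ``w_ng``, ``w_rec`` and ``w_tv`` weight the causality, reconstruction and
    total-variation components (all nonnegative; zero ablates a component).
    """

    w_ng: float = 1.0
    w_rec: float = 1.0
    w_tv: float = 1.0
    lr: float = 1e-2
    epochs: int = 400
    seed: int = 0
    joint_causality: bool = True
    pretrain_granger_epochs: int = 0

    def __post_init__(self):
        if min(self.w_ng, self.w_rec, self.w_tv) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def masked_loss(x, x_hat, mask):
    """Mean squared error over observed entries (mask = 1); 0 if none observed.

    Accepts arrays or tensors; returns a float for arrays, a scalar tensor
    when any input carries gradients.
    """
    symbolic = any(isinstance(a, Tensor) and (a.requires_grad or a._parents)
                   for a in (x, x_hat, mask))
    x, x_hat, mask = as_tensor(x), as_tensor(x_hat), as_tensor(mask)
    n_obs = float(mask.data.sum())
    if n_obs == 0:
        return Tensor(0.0) if symbolic else 0.0
    resid = (x - x_hat) * mask
    out = (resid**2).sum() * (1.0 / n_obs)
    return out if symbolic else out.item()


def tv_loss(x_hat):
    """Total variation: sum of absolute first differences along time, per attribute."""
    symbolic = isinstance(x_hat, Tensor) and (x_hat.requires_grad or x_hat._parents)
    x_hat = as_tensor(x_hat)
    if x_hat.ndim == 1:
        x_hat = x_hat.reshape(x_hat.shape[0], 1)
    if x_hat.shape[-2] < 2:
        return Tensor(0.0) if symbolic else 0.0
    diff = x_hat[..., 1:, :] - x_hat[..., :-1, :]
    out = diff.abs().sum()
    return out if symbolic else out.item()


def total_loss(l_ng, l_rec, l_tv, config: TrainingConfig):
    """Weighted sum of the three components per the training configuration."""
    if min(config.w_ng, config.w_rec, config.w_tv) < 0:
        raise ValueError("loss weights must be nonnegative")
    return config.w_ng * l_ng + config.w_rec * l_rec + config.w_tv * l_tv


def _granger_component(gmodel: GrangerModel, Xt: Tensor, M: np.ndarray,
                       lam: float, symbolic_penalty: bool = False):
    """Mean masked one-step error over all targets plus the scaled group penalty.

    With ``symbolic_penalty`` the penalty enters the computation graph (used
    for gradient checking); in the training loop it is instead handled by the
    proximal step, so only its value is added here.
    """
    total = Tensor(0.0)
    n_terms = max(M[:, 1:, :].sum(), 1.0)
    for j in range(gmodel.d):
        pred = _predict_t(gmodel.targets[j], Xt)
        resid = (Xt[:, 1:, j] - pred) * Tensor(M[:, 1:, j])
        total = total + (resid**2).sum()
    total = total * (1.0 / n_terms)
    pen = sum(group_penalty(t["W"] if symbolic_penalty else t["W"].data)
              for t in gmodel.targets)
    return total + lam * pen


def train(dataset: TimeSeriesDataset, granger_config: GrangerConfig,
          model_config: ImputationConfig, training_config: TrainingConfig
          ) -> tuple[ImputationModel, GrangerModel, dict]:
    """Jointly optimize the causal and imputation submodels with Adam.

    ``dataset`` must already be normalized to [0, 1]; windows of
    ``model_config.window_length`` form the (full) batch.  The history dict
    records the per-epoch component losses on their per-entry scales.
    """
    if training_config.pretrain_granger_epochs > 0:
        pre_cfg = GrangerConfig(**{**granger_config.__dict__,
                                   "epochs": training_config.pretrain_granger_epochs})
        gmodel, _ = fit_granger(dataset, pre_cfg)
    else:
        gmodel = GrangerModel(dataset.d, granger_config.hidden_size,
                              seed=granger_config.seed,
                              attribute_names=list(dataset.attribute_names))
    imodel = ImputationModel(dataset.d, model_config,
                             attribute_names=list(dataset.attribute_names))
    X, M, D = _stack_windows(dataset, model_config.window_length)
    Xt = Tensor(X)
    Mt = Tensor(M)
    n_tv = X[:, 1:, :].size  # entries of the first-difference array

    params = imodel.parameters()
    if training_config.w_ng > 0 or training_config.joint_causality:
        params = params + gmodel.parameters()
    opt = Adam(params, lr=training_config.lr)
    history = {"l_ng": [], "l_rec": [], "l_tv": [], "total": []}
    cfg = training_config
    for epoch in range(cfg.epochs):
        if cfg.w_ng > 0:
            l_ng = _granger_component(gmodel, Xt, M, granger_config.lam)
        else:
            l_ng = Tensor(0.0)
        A = _adjacency_t(gmodel)
        if not cfg.joint_causality:
            A = A.detach()
        x_hat = imodel._forward_t(Xt, D, A)
        l_rec = masked_loss(Xt, x_hat, Mt) if cfg.w_rec > 0 else Tensor(0.0)
        l_tv = tv_loss(x_hat) * (1.0 / n_tv) if cfg.w_tv > 0 else Tensor(0.0)
        loss = total_loss(l_ng, l_rec, l_tv, cfg)
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite total loss at epoch {epoch}: "
                f"ng={l_ng.data}, rec={l_rec.data}, tv={l_tv.data}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        if cfg.w_ng > 0:
            for t in gmodel.targets:
                t["W"].data = _prox_group(t["W"].data, cfg.lr * granger_config.lam)
        history["l_ng"].append(float(l_ng.data))
        history["l_rec"].append(float(l_rec.data))
        history["l_tv"].append(float(l_tv.data))
        history["total"].append(float(loss.data))
    from .granger import extract_adjacency
    imodel.adjacency = extract_adjacency(gmodel)
    return imodel, gmodel, history


def train_with_dropout_protocol(dataset: TimeSeriesDataset, p_train: float,
                                granger_config: GrangerConfig,
                                model_config: ImputationConfig,
                                training_config: TrainingConfig):
    """Training protocol with artificial drops on the training split.

    ``p_train`` of the observed entries are removed before training (their
    ground truth is kept only for monitoring, never entering the masked
    loss).  Returns (imputation model, granger model, history, eval_mask).
    """
    if p_train > 0:
        corrupted, eval_mask = inject_missing(dataset, p_train, training_config.seed)
    else:
        corrupted, eval_mask = dataset, np.zeros_like(dataset.mask)
    imodel, gmodel, history = train(corrupted, granger_config, model_config,
                                    training_config)
    return imodel, gmodel, history, eval_mask
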