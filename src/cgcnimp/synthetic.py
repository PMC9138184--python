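"""Granger-structured synthetic series with known causal graph and missingness.

The generator emulates the statistical structure the imputation model
assumes: a stationary multivariate series with sparse directed lag-1
dependencies among attributes, strong temporal autocorrelation, additive
Gaussian observation noise, and MCAR or block missingness at configurable
rates.  Because the true edge set and the complete ground truth are known,
both causal recovery and imputation accuracy are verifiable without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .timeseries import TimeSeriesDataset, apply_scaler, fit_scaler, inject_missing

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "Benchmark",
    "simulate_var",
    "simulate_nonlinear",
    "inject_blocks",
    "make_benchmark",
]

_BURN_IN = 200
_SPECTRAL_RADIUS = 0.9


@dataclass
class SimConfig:
    """Default study conditions for the synthetic benchmark."""

    d: int = 6
    n: int = 2000
    parents_per_node: int = 2
    coef_scale: float = 0.5
    noise_sd: float = 0.3
    self_lags: bool = True
    nonlinear: bool = False


@dataclass
class SyntheticDataset:
    """Fully observed ground-truth series plus its generating structure."""

    dataset: TimeSeriesDataset
    true_adjacency: np.ndarray  # binary; entry (i, j) = edge i -> j
    coefficients: np.ndarray    # C[j, i] = effect of attribute i on j at lag 1
    config: SimConfig
    seed: int


def _structure(d: int, parents_per_node: int, coef_scale: float, self_lags: bool,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if d < 2 or not 1 <= parents_per_node < d:
        raise ValueError("need d >= 2 and 1 <= parents_per_node < d")
    C = np.zeros((d, d))
    adj = np.zeros((d, d), dtype=np.int8)
    for j in range(d):
        others = [i for i in range(d) if i != j]
        parents = rng.choice(others, size=parents_per_node, replace=False)
        signs = rng.choice([-1.0, 1.0], size=parents_per_node)
        C[j, parents] = signs * coef_scale
        adj[parents, j] = 1
        if self_lags:
            C[j, j] = coef_scale
            adj[j, j] = 1
    return C, adj


def simulate_var(d: int, n: int, parents_per_node: int, coef_scale: float,
                 noise_sd: float, seed: int, self_lags: bool = True) -> SyntheticDataset:
    """Order-1 linear VAR with a sparse random parent structure.

    Each node gets exactly ``parents_per_node`` randomly chosen parents (plus
    an optional self-lag); the coefficient matrix is rescaled to spectral
    radius 0.9 so the process is stationary but strongly autocorrelated.  The
    first 200 burn-in steps are discarded.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(seed)
    C, adj = _structure(d, parents_per_node, coef_scale, self_lags, rng)
    rho = np.max(np.abs(np.linalg.eigvals(C)))
    if rho > 0:
        C = C * (_SPECTRAL_RADIUS / rho)
    x = np.zeros(d)
    out = np.empty((n, d))
    noise = rng.normal(0.0, noise_sd, size=(_BURN_IN + n, d))
    for t in range(_BURN_IN + n):
        x = C @ x + noise[t]
        if t >= _BURN_IN:
            out[t - _BURN_IN] = x
    cfg = SimConfig(d=d, n=n, parents_per_node=parents_per_node,
                    coef_scale=coef_scale, noise_sd=noise_sd, self_lags=self_lags)
    return SyntheticDataset(TimeSeriesDataset.from_values(out), adj, C, cfg, seed)


def simulate_nonlinear(d: int, n: int, parents_per_node: int, coef_scale: float,
                       noise_sd: float, seed: int, self_lags: bool = True
                       ) -> SyntheticDataset:
    """Same sparsity structure with a tanh link on each parent's contribution.

    ``x_t[j] = sum_i C[j, i] * tanh(x_{t-1}[i]) + noise``; the bounded link
    keeps the process stable without spectral rescaling.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(seed)
    C, adj = _structure(d, parents_per_node, coef_scale, self_lags, rng)
    x = np.zeros(d)
    out = np.empty((n, d))
    noise = rng.normal(0.0, noise_sd, size=(_BURN_IN + n, d))
    for t in range(_BURN_IN + n):
        x = C @ np.tanh(x) + noise[t]
        if t >= _BURN_IN:
            out[t - _BURN_IN] = x
    cfg = SimConfig(d=d, n=n, parents_per_node=parents_per_node,
                    coef_scale=coef_scale, noise_sd=noise_sd, self_lags=self_lags,
                    nonlinear=True)
    return SyntheticDataset(TimeSeriesDataset.from_values(out), adj, C, cfg, seed)


def inject_blocks(dataset: TimeSeriesDataset, block_length: int, block_rate: float,
                  seed: int) -> tuple[TimeSeriesDataset, np.ndarray]:
    """Remove contiguous runs per attribute until ~``block_rate`` of observed
    entries are dropped (emulates sensor outages / continuous gaps)."""
    if block_length < 1:
        raise ValueError("block_length must be >= 1")
    if block_length > dataset.n:
        raise ValueError("block_length exceeds series length")
    if not 0 <= block_rate < 1:
        raise ValueError("block_rate must satisfy 0 <= block_rate < 1")
    rng = np.random.default_rng(seed)
    target = int(np.rint(block_rate * dataset.n_observed))
    eval_mask = np.zeros_like(dataset.mask)
    mask = dataset.mask.copy()
    dropped = 0
    guard = 0
    while dropped < target and guard < 100000:
        guard += 1
        j = int(rng.integers(dataset.d))
        start = int(rng.integers(dataset.n - block_length + 1))
        stop = start + block_length
        # skip placements abutting an existing removal so no merged run can
        # exceed block_length
        lo, hi = max(0, start - 1), min(dataset.n, stop + 1)
        if eval_mask[lo:hi, j].any():
            continue
        hit = mask[start:stop, j] == 1
        eval_mask[start:stop, j][hit] = 1
        mask[start:stop, j][hit] = 0
        dropped += int(hit.sum())
    values = dataset.values.copy()
    values[eval_mask == 1] = np.nan
    corrupted = TimeSeriesDataset(values, mask, dataset.timestamps.copy(),
                                  list(dataset.attribute_names))
    return corrupted, eval_mask


@dataclass
class Benchmark:
    """Chronological 80/20 split with injected drops, on the normalized scale."""

    train: TimeSeriesDataset        # corrupted training split
    train_eval_mask: np.ndarray
    test: TimeSeriesDataset         # corrupted test split
    test_eval_mask: np.ndarray
    test_truth: TimeSeriesDataset   # fully observed normalized test split
    train_truth: TimeSeriesDataset
    scaler: object
    true_adjacency: np.ndarray
    config: SimConfig
    seed: int
    p_test: float


def make_benchmark(sim_config: SimConfig, p_test: float, seed: int,
                   p_train: float = 0.1, train_frac: float = 0.8) -> Benchmark:
    """Simulate, split 80/20 chronologically, normalize, and inject drops.

    The training split is corrupted at 10% (the training protocol); the test
    split at ``p_test``.  Normalization is min-max fitted on the observed
    training entries.
    """
    if not 0 < p_test < 1:
        raise ValueError("p_test must be in (0, 1)")
    sim = (simulate_nonlinear if sim_config.nonlinear else simulate_var)(
        sim_config.d, sim_config.n, sim_config.parents_per_node,
        sim_config.coef_scale, sim_config.noise_sd, seed,
        self_lags=sim_config.self_lags)
    full = sim.dataset
    n_train = int(np.rint(train_frac * full.n))
    if n_train < 2 or full.n - n_train < 2:
        raise ValueError("series too short for an 80/20 split")
    def _slice(a, b):
        return TimeSeriesDataset(full.values[a:b], full.mask[a:b],
                                 full.timestamps[a:b], list(full.attribute_names))
    train_truth_raw, test_truth_raw = _slice(0, n_train), _slice(n_train, full.n)
    scaler = fit_scaler(train_truth_raw)
    train_truth = apply_scaler(train_truth_raw, scaler)
    test_truth = apply_scaler(test_truth_raw, scaler)
    train, train_eval = inject_missing(train_truth, p_train, seed)
    test, test_eval = inject_missing(test_truth, p_test, seed + 1)
    return Benchmark(train, train_eval, test, test_eval, test_truth, train_truth,
                     scaler, sim.true_adjacency, sim_config, seed, p_test)
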