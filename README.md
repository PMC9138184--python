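# cgcnimp

Imputation of missing values in multivariate time series by a causal graph
convolutional network: a neural Granger causal-discovery submodel learns a
directed attribute-dependency graph, a graph-convolution layer mixes each
timestep's attributes through that graph, and a time-decay attention LSTM
reconstructs the series under a masked-reconstruction plus total-variation
multi-task objective, trained end to end.

The package is aimed at sensor-style data — air-quality stations, telemetry,
patient monitoring — where attributes drive one another with a lag, values
arrive at (possibly irregular) timestamps, and gaps appear from sensor
failure or transmission loss.

## Model

A series `X ∈ ℝ^{n×d}` carries a binary mask `M` (`M[t,j] = 1` iff observed)
and a time-lag matrix `δ` giving, per attribute, the elapsed time since the
last observation (gaps accumulate).  The method has three coupled parts:

1. **Neural Granger causality.**  One LSTM predictor per target attribute
   `j` forecasts `x[t,j]` from all attributes before `t`.  Its stacked gate
   input matrix `W⁽ʲ⁾` (4H × d) is penalized by a group lasso across input
   columns, so entire input groups are driven to exactly zero; the directed
   causal-strength matrix is `A[i,j] = ‖W⁽ʲ⁾ column group i‖²_F`.
   Optimization is Adam on the masked squared one-step error with a proximal
   group soft-threshold each step.
2. **Graph convolution.**  `A` is rescaled to max entry 1, self-looped and
   symmetrically degree-normalized, `Â = D^{-1/2}(A + I)D^{-1/2}`; each
   timestep's attribute vector is mixed by `Â` and passed through a shared
   feature transform with activation.
3. **Time-decay attention LSTM.**  A decay vector
   `α_t = 1/exp(max(0, W_α δ_t + b_α)) ∈ (0,1]` shrinks the recurrent hidden
   state according to staleness; the LSTM gates read `[α_t ⊙ h_{t-1}; H_G_t]`.
   Pairwise temporal attention (`softmax` of `exp(tanh(w·[h_i|h_j]))` scores)
   re-weights the hidden states and a linear head maps back to attribute
   values.

The joint objective is `w_ng·L_NG + w_rec·L_rec + w_tv·L_TV`: the causality
loss, the mean squared error over *observed* entries only, and the total
variation of the reconstruction (smooths noise while keeping jumps).
Imputation returns observed entries untouched and fills gaps with the
reconstruction.

Because real benchmark corpora are external, the package ships a synthetic
generator: sparse stationary VAR(1) (or tanh-link nonlinear) processes with a
known directed parent structure, plus MCAR and block missingness — so causal
recovery and imputation accuracy are verifiable end to end, offline.

## Worked example

```python
import cgcnimp as cg

# a 4-attribute Granger-structured series, 600 steps, 2 parents per node
sim = cg.simulate_var(d=4, n=600, parents_per_node=2, coef_scale=0.5,
                      noise_sd=0.3, seed=0)
ds = cg.apply_scaler(sim.dataset, cg.fit_scaler(sim.dataset))

# recover the causal graph
gmodel, _ = cg.fit_granger(ds, cg.GrangerConfig(seed=0))
A = cg.extract_adjacency(gmodel)
print("edge AUROC:", round(cg.causal_recovery_auroc(A, sim.true_adjacency), 3))

# 80/20 benchmark: train split corrupted at 10%, test split at 20%
bench = cg.make_benchmark(cg.SimConfig(d=4, n=600), p_test=0.2, seed=0)
imodel, _, history = cg.train(bench.train, cg.GrangerConfig(seed=0),
                              cg.ImputationConfig(seed=0),
                              cg.TrainingConfig(epochs=200, seed=0))
completed = cg.impute(imodel, bench.test, normalized=True)
r_model = cg.rmse(bench.test_truth.values, completed.values, bench.test_eval_mask)
mean_fill = cg.baseline_impute(bench.test, "mean")
r_mean = cg.rmse(bench.test_truth.values, mean_fill.values, bench.test_eval_mask)
print(f"model RMSE: {r_model:.4f}   mean-baseline RMSE: {r_mean:.4f}")
```

Output:

```
edge AUROC: 1.0
model RMSE: 0.1587   mean-baseline RMSE: 0.1597
```

The AUROC of 1.0 means ranking attribute pairs by the learned causal
strengths perfectly separates true lag-1 parents from non-edges.  The RMSE
values score only the artificially dropped test entries, on the normalized
0–1 scale; the trained imputer edges out the mean baseline on this small
problem, and the margin widens with longer series (see the reproduction
section).

A command-line interface mirrors the library:

```sh
cgcnimp --seed 1 --out-dir run simulate --d 6 --n 2000
cgcnimp --seed 1 --out-dir run causality run/series.csv
cgcnimp --seed 1 --out-dir run train run/series.csv
cgcnimp --seed 1 --out-dir run impute run/model.cgcn run/series.csv
cgcnimp --seed 1 --out-dir run evaluate --p-list 0.1,0.5,0.9
```

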