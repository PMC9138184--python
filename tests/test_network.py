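"""GCN, decay, attention and imputation forward-pass behaviour."""

import numpy as np
import pytest

import cgcnimp as cg
from cgcnimp.network import ImputationConfig, ImputationModel


def _decay_params(H, dg, rng):
    return {"W": rng.normal(size=(4 * H, H + dg)), "b": rng.normal(size=4 * H)}


class TestNormalizedAdjacency:
    def test_zero_adjacency_gives_identity(self):
        assert np.allclose(cg.normalized_adjacency(np.zeros((3, 3))), np.eye(3))

    def test_two_node_cycle(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.allclose(cg.normalized_adjacency(A), 0.5 * np.ones((2, 2)))

    def test_regular_graph_rows_sum_to_one(self):
        A = np.ones((4, 4)) - np.eye(4)
        got = cg.normalized_adjacency(A)
        assert np.allclose(got.sum(axis=1), 1.0)

    def test_max_rescaling_makes_result_scale_invariant(self, rng):
        A = np.abs(rng.normal(size=(4, 4)))
        assert np.allclose(cg.normalized_adjacency(A), cg.normalized_adjacency(17.0 * A))

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            cg.normalized_adjacency(np.array([[0.0, -1.0], [0.0, 0.0]]))

    def test_matches_dense_loop_oracle(self, rng):
        for _ in range(100):
            d = int(rng.integers(2, 5))
            A = np.abs(rng.normal(size=(d, d)))
            At = A / A.max() + np.eye(d)
            deg = At.sum(axis=1)
            oracle = np.zeros((d, d))
            for i in range(d):
                for j in range(d):
                    oracle[i, j] = At[i, j] / np.sqrt(deg[i] * deg[j])
            assert np.allclose(cg.normalized_adjacency(A), oracle, atol=1e-9)


class TestGcnForward:
    def test_identity_pipeline_returns_input(self, rng):
        X = rng.normal(size=(5, 3))
        out = cg.gcn_forward(X, np.eye(3), np.ones((1, 1)), activation="identity")
        assert np.allclose(out, X)

    def test_uniform_mixing_two_nodes(self):
        X = np.array([[1.0, 3.0], [2.0, 4.0]])
        out = cg.gcn_forward(X, 0.5 * np.ones((2, 2)), np.ones((1, 1)),
                             activation="identity")
        assert np.allclose(out, [[2.0, 2.0], [3.0, 3.0]])

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            n, d = int(rng.integers(1, 11)), int(rng.integers(2, 5))
            X = rng.normal(size=(n, d))
            A_hat = np.abs(rng.normal(size=(d, d)))
            theta = rng.normal(size=(1, 1))
            oracle = np.zeros((n, d))
            for t in range(n):
                for node in range(d):
                    mixed = sum(A_hat[node, k] * X[t, k] for k in range(d))
                    oracle[t, node] = np.tanh(mixed * theta[0, 0])
            got = cg.gcn_forward(X, A_hat, theta, activation="tanh")
            assert np.allclose(got, oracle, atol=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            cg.gcn_forward(rng.normal(size=(4, 3)), np.eye(2), np.ones((1, 1)))


class TestDecayVector:
    def test_zero_parameters_give_unit_decay(self):
        assert np.allclose(cg.decay_vector(np.array([3.0, 7.0]), np.zeros((2, 2)),
                                           np.zeros(2)), 1.0)

    def test_log_two_halves(self):
        got = cg.decay_vector(np.array([1.0]), np.array([[np.log(2.0)]]), np.zeros(1))
        assert np.allclose(got, 0.5)

    def test_always_in_unit_interval(self, rng):
        for _ in range(50):
            d, m = int(rng.integers(1, 5)), int(rng.integers(1, 6))
            a = cg.decay_vector(np.abs(rng.normal(size=d)) * 10,
                                rng.normal(size=(m, d)), rng.normal(size=m))
            assert np.all(a > 0) and np.all(a <= 1)

    def test_monotone_in_lag_for_nonnegative_weights(self, rng):
        W = np.abs(rng.normal(size=(3, 2)))
        b = rng.normal(size=3)
        d1 = np.array([1.0, 2.0])
        a1 = cg.decay_vector(d1, W, b)
        a2 = cg.decay_vector(d1 + 1.5, W, b)
        assert np.all(a2 <= a1 + 1e-12)


class TestDecayLstmStep:
    def test_unit_decay_is_standard_step(self, rng):
        H, dg = 3, 2
        p = _decay_params(H, dg, rng)
        h, s = rng.normal(size=H), rng.normal(size=H)
        hg = rng.normal(size=dg)
        got_h, got_s = cg.decay_lstm_step(h, s, hg, np.ones(H), p)
        # manual standard step, gate order i, f, s, o
        z = p["W"] @ np.concatenate([h, hg]) + p["b"]
        sig = lambda v: 1 / (1 + np.exp(-v))
        i, f = sig(z[:H]), sig(z[H:2 * H])
        g, o = np.tanh(z[2 * H:3 * H]), sig(z[3 * H:])
        s_ref = f * s + i * g
        assert np.allclose(got_s, s_ref, atol=1e-12)
        assert np.allclose(got_h, o * np.tanh(s_ref), atol=1e-12)

    def test_zero_decay_erases_hidden_contribution(self, rng):
        H, dg = 3, 2
        p = _decay_params(H, dg, rng)
        s, hg = rng.normal(size=H), rng.normal(size=dg)
        h1, s1 = cg.decay_lstm_step(rng.normal(size=H), s, hg, np.zeros(H), p)
        h2, s2 = cg.decay_lstm_step(rng.normal(size=H) * 5, s, hg, np.zeros(H), p)
        assert np.allclose(h1, h2) and np.allclose(s1, s2)

    def test_cell_state_not_decayed(self, rng):
        # with alpha = 0 the cell state still carries through the forget gate
        H, dg = 2, 1
        p = _decay_params(H, dg, rng)
        hg = np.zeros(dg)
        _, s_a = cg.decay_lstm_step(np.zeros(H), np.ones(H), hg, np.zeros(H), p)
        _, s_b = cg.decay_lstm_step(np.zeros(H), 2 * np.ones(H), hg, np.zeros(H), p)
        assert not np.allclose(s_a, s_b)

    def test_matches_scalar_loop_oracle(self, rng):
        sig = lambda v: 1 / (1 + np.exp(-v))
        for _ in range(100):
            H, dg = int(rng.integers(1, 5)), int(rng.integers(1, 4))
            p = _decay_params(H, dg, rng)
            h, s = rng.normal(size=H), rng.normal(size=H)
            hg, alpha = rng.normal(size=dg), rng.uniform(0.01, 1.0, size=H)
            inp = np.concatenate([alpha * h, hg])
            z = np.array([p["b"][r] + sum(p["W"][r, k] * inp[k]
                                          for k in range(H + dg))
                          for r in range(4 * H)])
            i, f = sig(z[:H]), sig(z[H:2 * H])
            g, o = np.tanh(z[2 * H:3 * H]), sig(z[3 * H:])
            s_ref = f * s + i * g
            h_ref = o * np.tanh(s_ref)
            got_h, got_s = cg.decay_lstm_step(h, s, hg, alpha, p)
            assert np.allclose(got_h, h_ref, atol=1e-9)
            assert np.allclose(got_s, s_ref, atol=1e-9)


class TestAttention:
    def test_single_step_is_identity(self, rng):
        H_L = rng.normal(size=(1, 4))
        atten, hp = cg.attention(H_L, rng.normal(size=8))
        assert np.allclose(atten, [[1.0]])
        assert np.allclose(hp, H_L)

    def test_zero_weight_gives_uniform_average(self, rng):
        H_L = rng.normal(size=(5, 3))
        atten, hp = cg.attention(H_L, np.zeros(6))
        assert np.allclose(atten, 0.2)
        assert np.allclose(hp, np.tile(H_L.mean(axis=0), (5, 1)))

    def test_rows_sum_to_one_entries_in_unit_interval(self, rng):
        for _ in range(30):
            T, H = int(rng.integers(1, 9)), int(rng.integers(1, 5))
            atten, _ = cg.attention(rng.normal(size=(T, H)), rng.normal(size=2 * H))
            assert np.allclose(atten.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(atten > 0) and np.all(atten < 1 + 1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            cg.attention(np.empty((0, 2)), np.zeros(4))


class TestReconstruct:
    def test_zero_weight_returns_bias(self):
        out = cg.reconstruct(np.random.default_rng(0).normal(size=(4, 3)),
                             np.zeros((2, 3)), np.array([1.0, -2.0]))
        assert np.allclose(out, np.tile([1.0, -2.0], (4, 1)))

    def test_affine_combination(self, rng):
        H1, H2 = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        W, b = rng.normal(size=(2, 3)), rng.normal(size=2)
        a = 0.3
        lhs = cg.reconstruct(a * H1 + (1 - a) * H2, W, b)
        rhs = a * cg.reconstruct(H1, W, b) + (1 - a) * cg.reconstruct(H2, W, b)
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestImpute:
    def _model(self, d, seed=0, window_length=10):
        cfg = ImputationConfig(hidden_size=8, window_length=window_length, seed=seed)
        model = ImputationModel(d, cfg, adjacency=np.zeros((d, d)))
        return model

    def test_fully_observed_returns_input(self, rng):
        ds = cg.TimeSeriesDataset.from_values(rng.uniform(size=(20, 3)))
        model = self._model(3)
        out = cg.impute(model, ds, normalized=True)
        assert np.array_equal(out.values, ds.values)

    def test_observed_entries_bit_identical(self, rng):
        vals = rng.uniform(size=(25, 3))
        vals[rng.random(vals.shape) < 0.3] = np.nan
        vals[0] = 0.5
        ds = cg.TimeSeriesDataset.from_values(vals)
        out = cg.impute(self._model(3, seed=4), ds, normalized=True)
        obs = ds.mask == 1
        assert np.array_equal(out.values[obs], ds.values[obs])
        assert not np.isnan(out.values).any()

    def test_outputs_finite_for_random_models(self, rng):
        for seed in range(5):
            vals = rng.uniform(size=(17, 4))
            vals[rng.random(vals.shape) < 0.5] = np.nan
            vals[0] = 0.1
            ds = cg.TimeSeriesDataset.from_values(vals)
            model = self._model(4, seed=seed, window_length=6)
            for k, t in model.params.items():
                t.data = t.data + rng.normal(0, 0.5, size=t.data.shape)
            out = cg.impute(model, ds, normalized=True)
            assert np.isfinite(out.values).all()

    def test_idempotent_on_completed_output(self, rng):
        vals = rng.uniform(size=(15, 2))
        vals[3, 1] = np.nan
        ds = cg.TimeSeriesDataset.from_values(vals)
        model = self._model(2, seed=9)
        once = cg.impute(model, ds, normalized=True)
        twice = cg.impute(model, once, normalized=True)
        assert np.array_equal(once.values, twice.values)

    def test_attribute_mismatch_rejected(self, rng):
        ds = cg.TimeSeriesDataset.from_values(rng.uniform(size=(8, 3)))
        with pytest.raises(ValueError):
            cg.impute(self._model(2), ds, normalized=True)

    def test_raw_scale_round_trip_through_scaler(self, rng):
        vals = rng.normal(10.0, 3.0, size=(20, 2))
        vals[5, 0] = np.nan
        ds = cg.TimeSeriesDataset.from_values(vals)
        model = self._model(2, seed=3)
        model.scaler = cg.fit_scaler(ds)
        out = cg.impute(model, ds)
        obs = ds.mask == 1
        assert np.array_equal(out.values[obs], ds.values[obs])
        assert np.isfinite(out.values).all()


class TestArchiveRoundTrip:
    def test_round_trip_reproduces_outputs_bitwise(self, rng, tmp_path):
        cfg = ImputationConfig(hidden_size=8, window_length=10, seed=2)
        model = ImputationModel(3, cfg, adjacency=np.abs(rng.normal(size=(3, 3))))
        model.scaler = cg.Scaler(mins=np.zeros(3), maxs=np.ones(3))
        vals = rng.uniform(size=(20, 3))
        vals[rng.random(vals.shape) < 0.3] = np.nan
        vals[0] = 0.2
        ds = cg.TimeSeriesDataset.from_values(vals)
        before = cg.impute(model, ds, normalized=True)
        path = tmp_path / "model.cgcn"
        model.save(path)
        loaded = cg.ImputationModel.load(path)
        after = cg.impute(loaded, ds, normalized=True)
        assert np.array_equal(before.values, after.values)
        assert loaded.attribute_names == model.attribute_names
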