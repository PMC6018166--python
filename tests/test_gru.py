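"""The recurrent cell is verified against an independently coded
scalar-loop evaluation of the gate equations, plus its analytic limits."""

import math

import numpy as np
import pytest

from slicegru import nn
from slicegru.gru import (
    GRUCellModule,
    GRUParams,
    SequenceClassifier,
    SequenceTrainConfig,
    build_sequence_classifier,
    gru_step,
    run_bgru,
    run_gru,
    select_group_slices,
    train_sequence_model,
)


def scalar_loop_step(p, x, h_prev):
    """Element-by-element re-evaluation of the update, one scalar at a time."""
    H, F = p.W_xz.shape
    z = np.empty(H)
    r = np.empty(H)
    for a in range(H):
        sz = sum(p.W_xz[a, b] * x[b] for b in range(F)) + sum(p.W_hz[a, b] * h_prev[b] for b in range(H))
        sr = sum(p.W_xr[a, b] * x[b] for b in range(F)) + sum(p.W_hr[a, b] * h_prev[b] for b in range(H))
        z[a] = 1.0 / (1.0 + math.exp(-sz))
        r[a] = 1.0 / (1.0 + math.exp(-sr))
    h_cand = np.empty(H)
    for a in range(H):
        s = sum(p.W_xh[a, b] * x[b] for b in range(F))
        s += sum(p.W_hh[a, b] * (h_prev[b] * r[b]) for b in range(H))
        h_cand[a] = math.tanh(s)
    h = np.array([(1.0 - z[a]) * h_cand[a] + z[a] * h_prev[a] for a in range(H)])
    return z, r, h_cand, h


def random_instance(rng, max_f=8, max_h=8):
    F = int(rng.integers(1, max_f + 1))
    H = int(rng.integers(1, max_h + 1))
    p = GRUParams.random(F, H, rng, scale=1.5)
    return p, F, H


class TestStepOracle:
    def test_200_random_instances_match_scalar_loop(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            p, F, H = random_instance(rng)
            n = int(rng.integers(1, 11))
            seq = rng.standard_normal((n, F)) * 2.0
            states = run_gru(p, seq)
            h = np.zeros(H)
            for i in range(n):
                z, r, h_cand, h = scalar_loop_step(p, seq[i], h)
                np.testing.assert_allclose(states[i], h, atol=1e-10, rtol=0)
            # trace of the final step agrees component-wise too
            trace = gru_step(p, seq[-1], states[-2] if n > 1 else np.zeros(H))
            np.testing.assert_allclose(trace.z_i, z, atol=1e-10, rtol=0)
            np.testing.assert_allclose(trace.r_i, r, atol=1e-10, rtol=0)
            np.testing.assert_allclose(trace.h_cand, h_cand, atol=1e-10, rtol=0)

    def test_zero_weights(self, rng):
        p = GRUParams(*(np.zeros((3, 4)),) * 1, W_hz=np.zeros((3, 3)), W_xr=np.zeros((3, 4)),
                      W_hr=np.zeros((3, 3)), W_xh=np.zeros((3, 4)), W_hh=np.zeros((3, 3)))
        x = rng.standard_normal(4)
        h_prev = rng.standard_normal(3)
        t = gru_step(p, x, h_prev)
        np.testing.assert_allclose(t.z_i, 0.5)
        np.testing.assert_allclose(t.r_i, 0.5)
        np.testing.assert_allclose(t.h_cand, 0.0)
        np.testing.assert_allclose(t.h_i, 0.5 * h_prev)

    def test_zero_input_zero_state(self, rng):
        p, F, H = random_instance(rng)
        t = gru_step(p, np.zeros(F), np.zeros(H))
        np.testing.assert_allclose(t.h_i, 0.0)

    def test_gate_and_state_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            F = int(rng.integers(1, 9))
            H = int(rng.integers(1, 9))
            p = GRUParams.random(F, H, rng)  # moderate weights: no float saturation
            seq = rng.standard_normal((6, F))
            h = np.zeros(H)
            for x in seq:
                t = gru_step(p, x, h)
                assert ((t.z_i > 0) & (t.z_i < 1)).all()
                assert ((t.r_i > 0) & (t.r_i < 1)).all()
                assert ((t.h_cand > -1) & (t.h_cand < 1)).all()
                assert ((t.h_i > -1) & (t.h_i < 1)).all()
                h = t.h_i

    def test_update_gate_copy_through_limit(self, rng):
        # drive z -> 1: huge positive update-gate preactivations copy h_0 through
        F, H = 4, 3
        p = GRUParams(
            W_xz=np.full((H, F), 1e3), W_hz=np.zeros((H, H)),
            W_xr=rng.standard_normal((H, F)), W_hr=rng.standard_normal((H, H)),
            W_xh=rng.standard_normal((H, F)), W_hh=rng.standard_normal((H, H)),
        )
        h0 = rng.uniform(-0.9, 0.9, H)
        seq = np.abs(rng.standard_normal((5, F))) + 0.1  # positive inputs
        states = run_gru(p, seq, h_0=h0)
        assert np.linalg.norm(states[-1] - h0) < 1e-6

    def test_shape_mismatch_rejected(self, rng):
        p, F, H = random_instance(rng)
        with pytest.raises(ValueError):
            gru_step(p, np.zeros(F + 1), np.zeros(H))
        with pytest.raises(ValueError):
            run_gru(p, np.zeros((3, F + 1)))


class TestRunGRU:
    def test_length_one_equals_single_step(self, rng):
        p, F, H = random_instance(rng)
        x = rng.standard_normal(F)
        np.testing.assert_array_equal(run_gru(p, x[None])[0], gru_step(p, x, np.zeros(H)).h_i)

    def test_matches_chained_steps(self, rng):
        p, F, H = random_instance(rng)
        seq = rng.standard_normal((5, F))
        states = run_gru(p, seq)
        h = np.zeros(H)
        for i in range(5):
            h = gru_step(p, seq[i], h).h_i
            np.testing.assert_allclose(states[i], h, atol=1e-12)


class TestBGRU:
    def test_backward_is_reversed_forward(self, rng):
        pf, F, H = random_instance(rng)
        pb = GRUParams.random(F, H, rng)
        seq = rng.standard_normal((6, F))
        out = run_bgru(pf, pb, seq)
        assert out.shape == (6, 2 * H)
        expected_bwd = run_gru(pb, seq[::-1])[::-1]
        np.testing.assert_array_equal(out[:, H:], expected_bwd)

    def test_palindrome_symmetry(self, rng):
        p, F, H = random_instance(rng)
        half = rng.standard_normal((3, F))
        seq = np.concatenate([half, half[::-1]])  # palindromic
        out = run_bgru(p, p, seq)
        fwd, bwd = out[:, :H], out[:, H:]
        # with shared weights the backward pass mirrors the forward one
        np.testing.assert_allclose(bwd, fwd[::-1], atol=1e-12)

    def test_input_dim_mismatch_rejected(self, rng):
        pf = GRUParams.random(4, 3, rng)
        pb = GRUParams.random(5, 3, rng)
        with pytest.raises(ValueError):
            run_bgru(pf, pb, np.zeros((4, 4)))


class TestSliceSelection:
    def test_equal_spacing_rule(self):
        # oracle: independent evaluation of round-half-up of j*(L-1)/(m-1)
        for L, m in [(15, 4), (10, 3), (20, 5), (7, 2)]:
            expected = [int(np.floor(j * (L - 1) / (m - 1) + 0.5)) for j in range(m)]
            assert select_group_slices(L, m) == expected
        assert select_group_slices(15, 4) == [0, 5, 9, 14]

    def test_identity_and_middle(self):
        assert select_group_slices(5, 5) == [0, 1, 2, 3, 4]
        assert select_group_slices(15, 1) == [7]

    def test_m_out_of_range(self):
        with pytest.raises(ValueError):
            select_group_slices(5, 6)
        with pytest.raises(ValueError):
            select_group_slices(5, 0)


class TestSequenceClassifier:
    def test_trainable_forward_matches_reference_recurrence(self, rng):
        model = SequenceClassifier(input_dim=4, seq_len=5, hidden_dim=3, fc_sizes=(6, 5), seed=1)
        seq = rng.standard_normal((5, 4))
        steps = [nn.Tensor(seq[i][None]) for i in range(5)]
        layer1 = model.layer1.run(steps)
        got = np.concatenate([s.data for s in layer1], axis=0)
        expected = run_bgru(model.layer1.fwd.to_params(), model.layer1.bwd.to_params(), seq)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_probabilities_sum_to_one(self, rng):
        model = build_sequence_classifier(hidden_dim=3, n_classes=2, input_dim=4, seq_len=6, fc_sizes=(8, 6))
        probs = model.predict_proba(rng.standard_normal((7, 6, 4)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_pre_dense_dimension_bookkeeping(self):
        n, H = 6, 3
        model = build_sequence_classifier(hidden_dim=H, n_classes=2, input_dim=4, seq_len=n)
        assert model.fc1.weight.shape[0] == n * 2 * H

    def test_zero_head_uniform_probabilities(self, rng):
        model = build_sequence_classifier(hidden_dim=3, n_classes=2, input_dim=4, seq_len=5)
        model.head.weight.data[:] = 0.0
        model.head.bias.data[:] = 0.0
        probs = model.predict_proba(rng.standard_normal((3, 5, 4)))
        np.testing.assert_allclose(probs, 0.5, atol=1e-12)

    def test_stacked_layer_consumes_2h(self):
        model = SequenceClassifier(input_dim=4, seq_len=5, hidden_dim=3, seed=0)
        assert model.layer2.fwd.input_dim == 2 * 3


def make_sequences(rng, n_per_class=20, seq_len=6, dim=5, offset=2.0):
    x0 = rng.standard_normal((n_per_class, seq_len, dim))
    x1 = rng.standard_normal((n_per_class, seq_len, dim)) + offset
    x = np.concatenate([x0, x1])
    y = np.repeat([0, 1], n_per_class)
    # sanity: a mean-threshold oracle already separates these perfectly
    means = x.mean(axis=(1, 2))
    assert ((means > offset / 2).astype(int) == y).mean() >= 0.95
    return x, y


class TestSequenceTraining:
    CFG = SequenceTrainConfig(learning_rate=5e-3, epochs=25, patience=25, batch_size=20,
                              hidden_dim=4, fc_sizes=(8, 6), dropout_rate=0.1, seed=0)

    def test_separable_sequences_learned(self, rng):
        x, y = make_sequences(rng)
        trained = train_sequence_model(x, y, x, y, self.CFG)
        assert trained.val_accuracy >= 0.9

    def test_shuffled_labels_at_chance(self, rng):
        x, y = make_sequences(rng)
        ysh = rng.permutation(y)
        cfg = SequenceTrainConfig(learning_rate=2e-3, epochs=6, patience=6, batch_size=20,
                                  hidden_dim=4, fc_sizes=(8, 6), seed=2)
        trained = train_sequence_model(x, ysh, x, rng.permutation(y), cfg)
        assert 0.25 <= trained.val_accuracy <= 0.80  # binomial(40) band around 0.5

    def test_fixed_seed_reproducible(self, rng):
        x, y = make_sequences(rng, n_per_class=8)
        a = train_sequence_model(x, y, x, y, self.CFG)
        b = train_sequence_model(x, y, x, y, self.CFG)
        assert a.val_losses == b.val_losses

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            train_sequence_model(np.zeros((0, 3, 2)), [], np.zeros((0, 3, 2)), [], self.CFG)
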