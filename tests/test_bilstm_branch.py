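import numpy as np
import pytest

from bipathnet.autodiff import Tensor
from bipathnet.bilstm_branch import (AttentionParams, LstmParams,
                                     attend_paths, encode_path,
                                     init_attention_params,
                                     init_lstm_params, lstm_step, run_lstm)
from bipathnet.data_io import ValidationError


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def scalar_lstm_oracle(X, params, conventional=False):
    """Element-by-element recurrence: gates f,i,o = sigma(Wg [h;x] + bg),
    c_hat = tanh(Wc [h;x] + bc), c = f*carry + i*c_hat, h = tanh(o*c);
    the carry is the previous candidate (default) or previous cell."""
    H = params.hidden_size
    Wg, bg = params.Wg.data, params.bg.data
    Wc, bc = params.Wc.data, params.bc.data
    h = np.zeros(H)
    carry = np.zeros(H)
    for x in X:
        hx = np.concatenate([h, x])
        gates = np.array([sigmoid(sum(hx[k] * Wg[k, m] for k in range(len(hx)))
                                  + bg[m]) for m in range(3 * H)])
        f, i, o = gates[:H], gates[H:2 * H], gates[2 * H:]
        c_hat = np.array([np.tanh(sum(hx[k] * Wc[k, m] for k in range(len(hx)))
                                  + bc[m]) for m in range(H)])
        c = f * carry + i * c_hat
        h = np.tanh(o * c)
        carry = c if conventional else c_hat
    return h


def attention_oracle(reps, params):
    """Hand-rolled u_i = tanh(Wp h_i + bp), alpha = softmax(u_i . u_p),
    v_p = sum alpha_i h_i."""
    Wp, bp, up = params.Wp.data, params.bp.data, params.up.data
    scores = [np.tanh(Wp.T @ h + bp) @ up for h in reps]
    e = np.exp(scores - np.max(scores))
    alpha = e / e.sum()
    vp = sum(a * h for a, h in zip(alpha, reps))
    return vp, alpha


def random_lstm_params(rng, V, H, direction="forward"):
    p = init_lstm_params(V, H, direction, rng)
    for t in p.tensors().values():
        t.data = rng.normal(scale=0.5, size=t.data.shape)
    return p


class TestLstmStep:
    def test_zero_parameters_give_half_gates_zero_hidden(self):
        rng = np.random.default_rng(0)
        p = init_lstm_params(4, 3, "forward", rng)
        for t in p.tensors().values():
            t.data = np.zeros_like(t.data)
        h, c, c_hat = lstm_step(Tensor(np.zeros(3)), Tensor(np.zeros(3)),
                                Tensor(rng.normal(size=4)), p)
        assert not c_hat.data.any() and not h.data.any()

    def test_activation_ranges(self):
        rng = np.random.default_rng(1)
        p = random_lstm_params(rng, 5, 4)
        h = Tensor(rng.uniform(-1, 1, 4))
        carry = Tensor(rng.normal(size=4))
        hn, c, c_hat = lstm_step(h, carry, Tensor(rng.normal(size=5)), p)
        assert (np.abs(hn.data) < 1).all()
        assert (np.abs(c_hat.data) < 1).all()

    def test_matches_scalar_oracle_over_sequences(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            V, H, L = 3, 3, int(rng.integers(2, 4))
            p = random_lstm_params(rng, V, H)
            X = rng.normal(size=(L, V))
            got = run_lstm(X[None], p).data[0]
            np.testing.assert_allclose(got, scalar_lstm_oracle(X, p),
                                       atol=1e-8)

    def test_conventional_variant_matches_oracle(self):
        rng = np.random.default_rng(3)
        p = random_lstm_params(rng, 4, 2)
        X = rng.normal(size=(3, 4))
        got = run_lstm(X[None], p, conventional=True).data[0]
        np.testing.assert_allclose(got,
                                   scalar_lstm_oracle(X, p, conventional=True),
                                   atol=1e-8)
        # the two recurrences genuinely differ on multi-step sequences
        assert not np.allclose(got, scalar_lstm_oracle(X, p))

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        p = init_lstm_params(4, 3, "forward", rng)
        with pytest.raises(ValueError, match="mismatch"):
            lstm_step(Tensor(np.zeros(3)), Tensor(np.zeros(3)),
                      Tensor(np.zeros(7)), p)


class TestEncodePath:
    def test_palindrome_with_tied_parameters(self):
        rng = np.random.default_rng(5)
        p = random_lstm_params(rng, 4, 3)
        x, y = rng.normal(size=4), rng.normal(size=4)
        emb = np.stack([x, y, x])  # reads the same in both directions
        h = encode_path(emb, p, p).data
        np.testing.assert_allclose(h[:3], h[3:], atol=1e-12)

    def test_two_node_path_matches_step_composition(self):
        rng = np.random.default_rng(6)
        fwd = random_lstm_params(rng, 4, 2)
        bwd = random_lstm_params(rng, 4, 2, "backward")
        emb = rng.normal(size=(2, 4))
        h = encode_path(emb, fwd, bwd).data
        np.testing.assert_allclose(h[:2], scalar_lstm_oracle(emb, fwd),
                                   atol=1e-8)
        np.testing.assert_allclose(h[2:], scalar_lstm_oracle(emb[::-1], bwd),
                                   atol=1e-8)

    def test_zero_parameters_zero_representation(self):
        rng = np.random.default_rng(7)
        fwd = init_lstm_params(4, 3, "forward", rng)
        bwd = init_lstm_params(4, 3, "backward", rng)
        for p in (fwd, bwd):
            for t in p.tensors().values():
                t.data = np.zeros_like(t.data)
        h = encode_path(np.ones((3, 4)), fwd, bwd).data
        assert not h.any()

    def test_empty_sequence_rejected(self):
        rng = np.random.default_rng(8)
        p = init_lstm_params(4, 3, "forward", rng)
        with pytest.raises(ValidationError):
            encode_path(np.zeros((0, 4)), p, p)


class TestAttention:
    def test_single_path_gets_weight_one(self):
        rng = np.random.default_rng(9)
        params = init_attention_params(2, rng)
        h = Tensor(rng.normal(size=4))
        vp, alpha = attend_paths([h], params)
        np.testing.assert_allclose(alpha, [1.0])
        np.testing.assert_allclose(vp.data, h.data, atol=1e-12)

    def test_identical_paths_share_weight_uniformly(self):
        rng = np.random.default_rng(10)
        params = init_attention_params(3, rng)
        h = Tensor(rng.normal(size=6))
        _, alpha = attend_paths([h, h, h, h], params)
        np.testing.assert_allclose(alpha, 0.25, atol=1e-12)

    def test_matches_hand_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            params = init_attention_params(3, rng)
            reps = [rng.normal(size=6) for _ in range(3)]
            vp, alpha = attend_paths([Tensor(r) for r in reps], params)
            vp_o, alpha_o = attention_oracle(reps, params)
            np.testing.assert_allclose(alpha, alpha_o, atol=1e-8)
            np.testing.assert_allclose(vp.data, vp_o, atol=1e-8)

    def test_weights_normalized_and_nonnegative(self):
        rng = np.random.default_rng(12)
        params = init_attention_params(4, rng)
        reps = [Tensor(rng.normal(size=8)) for _ in range(7)]
        _, alpha = attend_paths(reps, params)
        assert alpha.sum() == pytest.approx(1.0, abs=1e-6)
        assert (alpha >= 0).all()

    def test_path_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        params = init_attention_params(3, rng)
        reps = [rng.normal(size=6) for _ in range(5)]
        perm = [3, 0, 4, 1, 2]
        vp1, a1 = attend_paths([Tensor(r) for r in reps], params)
        vp2, a2 = attend_paths([Tensor(reps[p]) for p in perm], params)
        np.testing.assert_allclose(a2, a1[perm], atol=1e-12)
        np.testing.assert_allclose(vp2.data, vp1.data, atol=1e-10)

    def test_empty_path_set_gives_zero_vector(self):
        rng = np.random.default_rng(14)
        params = init_attention_params(3, rng)
        vp, alpha = attend_paths([], params)
        assert vp.data.shape == (6,) and not vp.data.any()
        assert alpha.size == 0
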