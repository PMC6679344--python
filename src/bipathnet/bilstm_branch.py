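"""Sequence branch: a bidirectional LSTM over each path plus path-level
attention, producing the "path representation" v_p of a pair.

The recurrence follows the source formulation exactly, which differs
from a textbook LSTM in one place: the cell update mixes the *previous
candidate* state rather than the previous cell state,

    gates f,i,o = sigmoid(W_g [h_prev ; x] + b_g)
    c_hat       = tanh(W_c [h_prev ; x] + b_c)
    c           = f * c_hat_prev + i * c_hat        (default)
    h           = tanh(o * c)

A `conventional` switch restores the standard  c = f * c_prev + i * c_hat.
Each path is encoded as the concatenation of the terminal forward and
backward hidden states (length 2H); a pair's paths are fused by softmax
attention against a learned context vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, segment_softmax, segment_sum
from .data_io import ValidationError

__all__ = ["LstmParams", "AttentionParams", "init_lstm_params",
           "init_attention_params", "lstm_step", "run_lstm", "encode_path",
           "attend_paths", "attend_path_batch"]


@dataclass
class LstmParams:
    """One direction's gate and candidate parameters.

    W_g maps [h ; x] (H + V) to the three stacked gates (3H, order f, i, o);
    W_c maps the same input to the candidate state (H).
    """
    direction: str
    Wg: Tensor  # (H+V, 3H)
    bg: Tensor  # (3H,)
    Wc: Tensor  # (H+V, H)
    bc: Tensor  # (H,)
    hidden_size: int

    def tensors(self):
        p = f"lstm.{self.direction}"
        return {f"{p}.Wg": self.Wg, f"{p}.bg": self.bg,
                f"{p}.Wc": self.Wc, f"{p}.bc": self.bc}


@dataclass
class AttentionParams:
    """Path-level attention: projection (W_p, b_p) and context vector u_p."""
    Wp: Tensor  # (2H, 2H)
    bp: Tensor  # (2H,)
    up: Tensor  # (2H,)

    def tensors(self):
        return {"attn.Wp": self.Wp, "attn.bp": self.bp, "attn.up": self.up}


def _glorot(rng, shape):
    bound = np.sqrt(6.0 / sum(shape))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


def init_lstm_params(input_size: int, hidden_size: int, direction: str,
                     rng) -> LstmParams:
    hv = hidden_size + input_size
    return LstmParams(
        direction=direction,
        Wg=_glorot(rng, (hv, 3 * hidden_size)),
        bg=Tensor(np.zeros(3 * hidden_size), requires_grad=True),
        Wc=_glorot(rng, (hv, hidden_size)),
        bc=Tensor(np.zeros(hidden_size), requires_grad=True),
        hidden_size=hidden_size,
    )


def init_attention_params(hidden_size: int, rng) -> AttentionParams:
    h2 = 2 * hidden_size
    return AttentionParams(Wp=_glorot(rng, (h2, h2)),
                           bp=Tensor(np.zeros(h2), requires_grad=True),
                           up=_glorot(rng, (h2,)))


def lstm_step(prev_h, prev_state, x, params: LstmParams):
    """One recurrence step on a (P, V) batch of node vectors.

    `prev_state` is whatever the cell update mixes with the forget gate:
    the previous candidate in the default formulation, the previous cell
    state in the conventional one — the step itself is agnostic and
    returns (h, c, c_hat) so the caller picks the carry.
    """
    H = params.hidden_size
    for name, t in (("prev_h", prev_h), ("prev_state", prev_state),
                    ("x", x)):
        if not isinstance(t, Tensor):
            raise TypeError(f"{name} must be a Tensor")
    if prev_h.shape[-1] != H or x.shape[-1] + H != params.Wg.shape[0]:
        raise ValueError(
            f"dimension mismatch: h {prev_h.shape}, x {x.shape}, "
            f"Wg {params.Wg.shape}")
    hx = concat([prev_h, x], axis=-1)
    gates = (hx @ params.Wg + params.bg).sigmoid()
    if gates.ndim == 1:
        f, i, o = gates[:H], gates[H:2 * H], gates[2 * H:]
    else:
        f, i, o = gates[:, :H], gates[:, H:2 * H], gates[:, 2 * H:]
    c_hat = (hx @ params.Wc + params.bc).tanh()
    c = f * prev_state + i * c_hat
    h = (o * c).tanh()
    return h, c, c_hat


def run_lstm(X: np.ndarray, params: LstmParams,
             conventional: bool = False) -> Tensor:
    """Run one direction over a (P, L, V) batch of equal-length sequences;
    returns the terminal hidden states (P, H). Initial h and carry are 0."""
    P, L, V = X.shape
    H = params.hidden_size
    h = Tensor(np.zeros((P, H)))
    carry = Tensor(np.zeros((P, H)))
    for j in range(L):
        h, c, c_hat = lstm_step(h, carry, Tensor(X[:, j, :]), params)
        carry = c if conventional else c_hat
    return h


def encode_path(embeddings: np.ndarray, fwd: LstmParams, bwd: LstmParams,
                conventional: bool = False) -> Tensor:
    """Bidirectional encoding h_i = h_l^f concat h_l^b of one (L, V) path."""
    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.ndim != 2 or embeddings.shape[0] == 0:
        raise ValidationError("path embedding sequence must be non-empty (L, V)")
    X = embeddings[None]  # (1, L, V)
    hf = run_lstm(X, fwd, conventional)
    hb = run_lstm(X[:, ::-1], bwd, conventional)
    return concat([hf, hb], axis=1).reshape(-1)


def attend_paths(reps, params: AttentionParams):
    """Fuse the encoded paths of one pair: (v_p, attention weights).

    With no paths at all, v_p is a zero vector and the weights are empty;
    callers mask such pairs out of the path-branch loss and score.
    """
    h2 = params.up.shape[0]
    if len(reps) == 0:
        return Tensor(np.zeros(h2)), np.zeros(0)
    H = concat([r.reshape(1, -1) for r in reps], axis=0)  # (n, 2H)
    vp, alpha = attend_path_batch(H, np.zeros(len(reps), dtype=int), 1,
                                  params)
    return vp.reshape(-1), alpha.data


def attend_path_batch(H: Tensor, seg: np.ndarray, n_pairs: int,
                      params: AttentionParams):
    """Attention over a ragged batch: rows of H are path encodings, `seg`
    maps each to its pair. Returns (v_p (n_pairs, 2H), alpha (rows,))."""
    u = (H @ params.Wp + params.bp).tanh()
    scores = u @ params.up
    alpha = segment_softmax(scores, seg)
    weighted = alpha.reshape(-1, 1) * H
    vp = segment_sum(weighted, seg, n_pairs)
    return vp, alpha
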