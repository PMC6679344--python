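"""Model assembly and optimization.

The full model scores a drug-disease pair with two softmax heads,

    s_n = softmax(W_n v_n + b_n)        (convolutional branch)
    s_p = softmax(W_p v_p + b_p)        (path branch)
    s   = lambda * s_n + (1 - lambda) * s_p,

and trains both branches jointly on the unweighted sum of their
cross-entropy losses; the combination weight lambda enters only the
score. Training pairs are the known associations of the training folds
plus an equal number of never-associated pairs sampled uniformly without
replacement. Pairs that have no path in the (leakage-masked) network
contribute only the convolutional branch to loss and score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import autodiff
from .autodiff import Tensor, concat, log_softmax
from . import cnn_branch as cnn
from . import bilstm_branch as blstm
from .cnn_branch import ConvBranchParams
from .bilstm_branch import LstmParams, AttentionParams
from .data_io import RunConfig, ValidationError
from .features import embedding_matrix, enumerate_paths
from .similarity import HeterogeneousNetwork

log = logging.getLogger(__name__)

__all__ = ["ModelState", "TrainingSet", "init_model", "sample_negatives",
           "make_folds", "pair_scores", "losses", "train", "score_pairs",
           "PairBatch", "build_pair_batch", "forward_batch", "batch_losses",
           "gather_parameters", "AdamOptimizer"]

N_CLASSES = 2


@dataclass
class ModelState:
    """Every learnable tensor of both branches and both heads, plus lambda."""
    conv: ConvBranchParams
    lstm_fwd: LstmParams
    lstm_bwd: LstmParams
    attention: AttentionParams
    Wn: Tensor  # (len(v_n), 2)
    bn: Tensor  # (2,)
    Wp_head: Tensor  # (2H, 2)
    bp_head: Tensor  # (2,)
    combine_weight: float
    conventional_lstm: bool = False

    def tensors(self) -> dict:
        out = {}
        out.update(self.conv.tensors())
        out.update(self.lstm_fwd.tensors())
        out.update(self.lstm_bwd.tensors())
        out.update(self.attention.tensors())
        out.update({"head_n.W": self.Wn, "head_n.b": self.bn,
                    "head_p.W": self.Wp_head, "head_p.b": self.bp_head})
        return out


@dataclass
class TrainingSet:
    """Balanced positives/negatives with fold assignments (index pairs)."""
    positives: list          # [(drug_idx, disease_idx)]
    negatives: list
    pos_folds: np.ndarray    # fold id per positive
    neg_folds: np.ndarray

    def fold_split(self, fold: int):
        """(train_pairs, train_labels, test_positives) for one fold."""
        train, labels = [], []
        for p, f in zip(self.positives, self.pos_folds):
            if f != fold:
                train.append(p)
                labels.append(1)
        for p, f in zip(self.negatives, self.neg_folds):
            if f != fold:
                train.append(p)
                labels.append(0)
        test_pos = [p for p, f in zip(self.positives, self.pos_folds)
                    if f == fold]
        return train, np.asarray(labels), test_pos


def init_model(n_features: int, config: RunConfig, rng) -> ModelState:
    H = config.lstm_hidden_size
    vn_len = cnn.vn_length(n_features, config)
    # softmax heads start at zero so the initial score is uninformative
    # (loss = ln 2 per head and pair) regardless of representation scale
    return ModelState(
        conv=cnn.init_conv_params(n_features, config, rng),
        lstm_fwd=blstm.init_lstm_params(n_features, H, "forward", rng),
        lstm_bwd=blstm.init_lstm_params(n_features, H, "backward", rng),
        attention=blstm.init_attention_params(H, rng),
        Wn=Tensor(np.zeros((vn_len, N_CLASSES)), requires_grad=True),
        bn=Tensor(np.zeros(N_CLASSES), requires_grad=True),
        Wp_head=Tensor(np.zeros((2 * H, N_CLASSES)), requires_grad=True),
        bp_head=Tensor(np.zeros(N_CLASSES), requires_grad=True),
        combine_weight=config.combine_weight,
        conventional_lstm=config.conventional_lstm,
    )


def gather_parameters(state: ModelState) -> dict:
    return {k: t for k, t in state.tensors().items() if t.requires_grad}


# -- training-set construction ----------------------------------------------

def sample_negatives(A: np.ndarray, n_pos: int, seed) -> list:
    """Uniform sample of `n_pos` distinct zero entries of A."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    zi, zj = np.nonzero(A == 0)
    if len(zi) < n_pos:
        raise ValidationError(
            f"cannot sample {n_pos} negatives from {len(zi)} zero entries")
    pick = rng.choice(len(zi), size=n_pos, replace=False)
    return [(int(zi[k]), int(zj[k])) for k in pick]


def make_folds(positives, negatives, k: int, seed):
    """Random k-fold assignment of positives and negatives separately;
    fold sizes differ by at most one within each class."""
    if k < 2:
        raise ValidationError("folds must be >= 2")
    if len(positives) < k:
        raise ValidationError(
            f"{len(positives)} positives cannot fill {k} folds")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    def assign(n):
        ids = np.arange(n) % k          # balanced counts
        return ids[rng.permutation(n)]
    return TrainingSet(positives=list(positives), negatives=list(negatives),
                       pos_folds=assign(len(positives)),
                       neg_folds=assign(len(negatives)))


# -- batched forward --------------------------------------------------------

@dataclass
class PairBatch:
    """Dense inputs for a batch of pairs: feature matrices plus the ragged
    path tensor grouped by path length."""
    pairs: list
    F: np.ndarray                     # (B, 2, V)
    path_groups: dict = field(default_factory=dict)  # L -> (P_L, L) index array
    seg_groups: dict = field(default_factory=dict)   # L -> (P_L,) pair index
    has_paths: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))


def build_pair_batch(net: HeterogeneousNetwork, pairs, config: RunConfig,
                     E: np.ndarray | None = None) -> PairBatch:
    """Assemble features and (leakage-masked) path sets for index pairs.

    `pairs` are (drug_idx, disease_idx). The direct edge of each pair is
    excluded from its own path enumeration; test-fold edges must already
    be absent from `net` (see HeterogeneousNetwork.masked).
    """
    if E is None:
        E = embedding_matrix(net)
    nr = net.n_drugs
    B = len(pairs)
    F = np.stack([np.vstack([E[i], E[nr + j]]) for i, j in pairs])
    # a training positive's own edge appears inside its feature rows at
    # two diagonal-marked positions; zero them so the label of the query
    # pair can never be read off its own features (test pairs read 0
    # there anyway, so this also aligns train and test distributions)
    for b, (i, j) in enumerate(pairs):
        F[b, 0, nr + j] = 0.0
        F[b, 1, i] = 0.0
    groups, segs = {}, {}
    has_paths = np.zeros(B, dtype=bool)
    for b, (i, j) in enumerate(pairs):
        ps = enumerate_paths(net, net.drug_ids[i], net.disease_ids[j],
                             max_len=config.max_path_len,
                             max_paths=config.max_paths_per_pair)
        if len(ps) == 0:
            continue
        has_paths[b] = True
        for p in ps.index_paths:
            L = len(p)
            groups.setdefault(L, []).append(p)
            segs.setdefault(L, []).append(b)
    return PairBatch(
        pairs=list(pairs), F=F,
        path_groups={L: np.asarray(v) for L, v in groups.items()},
        seg_groups={L: np.asarray(v) for L, v in segs.items()},
        has_paths=has_paths,
    )


def forward_batch(state: ModelState, batch: PairBatch, E: np.ndarray):
    """Both branches on a batch; returns (logits_n, logits_p, vp)."""
    B = len(batch.pairs)
    vn = cnn.cnn_branch_forward(batch.F, state.conv)
    logits_n = vn @ state.Wn + state.bn

    reps, segs = [], []
    for L in sorted(batch.path_groups):
        idx = batch.path_groups[L]               # (P_L, L)
        X = E[idx].copy()                        # (P_L, L, V)
        seg = batch.seg_groups[L]
        # every path starts at the query drug and ends at the query
        # disease; blank the pair's own association entry in both
        # terminal embeddings (cf. the F masking in build_pair_batch)
        rows = np.arange(len(idx))
        X[rows, 0, idx[:, -1]] = 0.0             # A[s, t] inside x_s
        X[rows, -1, idx[:, 0]] = 0.0             # A[s, t] inside x_t
        hf = blstm.run_lstm(X, state.lstm_fwd, state.conventional_lstm)
        hb = blstm.run_lstm(X[:, ::-1], state.lstm_bwd,
                            state.conventional_lstm)
        reps.append(concat([hf, hb], axis=1))
        segs.append(seg)
    if reps:
        H_all = concat(reps, axis=0) if len(reps) > 1 else reps[0]
        seg_all = np.concatenate(segs)
        vp, _ = blstm.attend_path_batch(H_all, seg_all, B, state.attention)
    else:
        vp = Tensor(np.zeros((B, 2 * state.lstm_fwd.hidden_size)))
    logits_p = vp @ state.Wp_head + state.bp_head
    return logits_n, logits_p


# -- scores and losses ------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def pair_scores(state: ModelState, v_n, v_p, has_paths: bool = True):
    """Combined score of one pair from its branch representations.

    Returns (s_n, s_p, s) as length-2 distributions; s = s_n when the
    pair has no paths.
    """
    v_n = np.asarray(v_n, dtype=float)
    v_p = np.asarray(v_p, dtype=float)
    s_n = _softmax(v_n @ state.Wn.data + state.bn.data)
    s_p = _softmax(v_p @ state.Wp_head.data + state.bp_head.data)
    lam = state.combine_weight
    s = lam * s_n + (1 - lam) * s_p if has_paths else s_n
    return s_n, s_p, s


def losses(s_n: np.ndarray, s_p: np.ndarray, label_onehot: np.ndarray,
           path_mask=None):
    """Summed cross-entropies of the two heads over a batch (pure NumPy;
    the training loop uses the autodiff twin `batch_losses`). Probabilities
    are clamped at 1e-12 before the log."""
    s_n = np.clip(np.atleast_2d(s_n), 1e-12, None)
    s_p = np.clip(np.atleast_2d(s_p), 1e-12, None)
    y = np.atleast_2d(label_onehot)
    loss_n = -(y * np.log(s_n)).sum()
    per_p = -(y * np.log(s_p)).sum(axis=1)
    if path_mask is not None:
        per_p = per_p * np.asarray(path_mask, dtype=float)
    return float(loss_n), float(per_p.sum())


def batch_losses(logits_n: Tensor, logits_p: Tensor, labels: np.ndarray,
                 has_paths: np.ndarray):
    """Differentiable summed cross-entropies; path-free pairs are masked
    out of the path-branch term."""
    B = len(labels)
    y = np.zeros((B, N_CLASSES))
    y[np.arange(B), labels] = 1.0
    ln = log_softmax(logits_n, axis=-1)
    lp = log_softmax(logits_p, axis=-1)
    loss_n = -(Tensor(y) * ln).sum()
    mask = has_paths.astype(float).reshape(-1, 1)
    loss_p = -(Tensor(y * mask) * lp).sum()
    return loss_n, loss_p


# -- optimizer --------------------------------------------------------------

class AdamOptimizer:
    """Adam with the published defaults (beta1 0.9, beta2 0.999, eps 1e-8)."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


# -- training loop ----------------------------------------------------------

def train(net: HeterogeneousNetwork, train_pairs, train_labels,
          config: RunConfig, rng, state: ModelState | None = None):
    """Optimize both branches on the given pairs.

    `net` must already have test-fold association edges removed. Path sets
    are enumerated once up front (the direct edge of each pair is excluded
    from its own paths); batches are reshuffled every epoch.

    Returns (state, history) where history has one row per epoch:
    (loss_n, loss_p, total), each summed over the epoch.
    """
    old_dtype = autodiff.set_default_dtype(config.dtype)
    try:
        return _train_impl(net, train_pairs, train_labels, config, rng,
                           state)
    finally:
        autodiff.set_default_dtype(old_dtype)


def _train_impl(net, train_pairs, train_labels, config, rng, state):
    E = embedding_matrix(net).astype(autodiff.default_dtype())
    V = E.shape[1]
    if state is None:
        state = init_model(V, config, rng)
    params = gather_parameters(state)
    opt = AdamOptimizer(params, lr=config.learning_rate)

    train_labels = np.asarray(train_labels)
    batch = build_pair_batch(net, train_pairs, config, E)
    n = len(train_pairs)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_n = ep_p = 0.0
        for lo in range(0, n, config.batch_size):
            sel = order[lo:lo + config.batch_size]
            sub = _subset_batch(batch, sel)
            logits_n, logits_p = forward_batch(state, sub, E)
            loss_n, loss_p = batch_losses(logits_n, logits_p,
                                          train_labels[sel], sub.has_paths)
            total = loss_n + loss_p
            if not np.isfinite(total.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: "
                    f"loss_n={loss_n.data}, loss_p={loss_p.data}")
            opt.zero_grad()
            total.backward()
            opt.step()
            ep_n += float(loss_n.data)
            ep_p += float(loss_p.data)
        history.append((ep_n, ep_p, ep_n + ep_p))
        log.info("epoch %d: loss_n=%.4f loss_p=%.4f total=%.4f",
                 epoch, ep_n, ep_p, ep_n + ep_p)
    return state, np.asarray(history)


def _subset_batch(batch: PairBatch, sel: np.ndarray) -> PairBatch:
    """Restrict a prebuilt PairBatch to a subset of pair positions."""
    remap = -np.ones(len(batch.pairs), dtype=int)
    remap[sel] = np.arange(len(sel))
    groups, segs = {}, {}
    for L, idx in batch.path_groups.items():
        seg = batch.seg_groups[L]
        keep = remap[seg] >= 0
        if keep.any():
            groups[L] = idx[keep]
            segs[L] = remap[seg[keep]]
    return PairBatch(pairs=[batch.pairs[s] for s in sel],
                     F=batch.F[sel],
                     path_groups=groups, seg_groups=segs,
                     has_paths=batch.has_paths[sel])


def score_pairs(state: ModelState, net: HeterogeneousNetwork, pairs,
                config: RunConfig, batch_size: int = 512,
                E: np.ndarray | None = None) -> np.ndarray:
    """Association scores (class-1 components) for index pairs.

    Returns an (n, 3) array of columns (s_n, s_p, combined); pairs with
    no paths get combined = s_n and s_p = nan.
    """
    old_dtype = autodiff.set_default_dtype(config.dtype)
    try:
        if E is None:
            E = embedding_matrix(net)
        E = E.astype(autodiff.default_dtype(), copy=False)
        out = np.zeros((len(pairs), 3))
        lam = state.combine_weight
        for lo in range(0, len(pairs), batch_size):
            chunk = pairs[lo:lo + batch_size]
            batch = build_pair_batch(net, chunk, config, E)
            logits_n, logits_p = forward_batch(state, batch, E)
            s_n = _softmax(logits_n.data)[:, 1]
            s_p = _softmax(logits_p.data)[:, 1]
            s = lam * s_n + (1 - lam) * s_p
            s = np.where(batch.has_paths, s, s_n)
            s_p = np.where(batch.has_paths, s_p, np.nan)
            out[lo:lo + len(chunk)] = np.column_stack([s_n, s_p, s])
        return out
    finally:
        autodiff.set_default_dtype(old_dtype)
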