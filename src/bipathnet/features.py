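"""Pair-level inputs for the two model branches.

For a drug-disease pair (r_i, d_j) the convolutional branch consumes a
2×(Nr+Nd) feature matrix F that splices similarities and associations:

    F[0] = R_i  concat  A_i.      (drug row: similarities, then associations)
    F[1] = A_.j concat  D_j.      (disease row: associations, then similarities)

The sequence branch consumes the set of bounded-length simple paths from
r_i to d_j through the heterogeneous network; each node on a path is
embedded with the same (Nr+Nd)-dimensional vector its row in F would
have. The direct association edge between the query pair — and any edge
listed in a leakage mask, e.g. held-out test-fold labels — is removed
before traversal so that a label can never leak into its own features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .similarity import HeterogeneousNetwork

__all__ = ["PairFeatureMatrix", "PathSet", "embedding_matrix",
           "build_pair_features", "enumerate_paths", "embed_path"]


@dataclass
class PairFeatureMatrix:
    drug_id: str
    disease_id: str
    F: np.ndarray  # (2, Nr+Nd)


@dataclass
class PathSet:
    """Simple paths r_s -> ... -> d_t with node-index sequences and weights.

    `index_paths` holds global node indices (drugs 0..Nr-1, diseases
    Nr..Nr+Nd-1); `paths` the same sequences as entity-ID strings.
    `weights` is the product of traversed edge weights per path. Paths are
    ordered by descending weight, ties broken by the ID sequence, and
    truncated to `max_paths`.
    """
    source: str
    target: str
    paths: list = field(default_factory=list)
    index_paths: list = field(default_factory=list)
    weights: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __len__(self):
        return len(self.paths)


def embedding_matrix(net: HeterogeneousNetwork) -> np.ndarray:
    """Stacked node embeddings, one row per node (drugs then diseases):

        E = [ R  | A ]
            [ A' | D ]

    Row k of E is the feature vector of node k used both in F and in
    path sequences.
    """
    top = np.hstack([net.R.values, net.A])
    bottom = np.hstack([net.A.T, net.D.values])
    return np.vstack([top, bottom])


def build_pair_features(net: HeterogeneousNetwork, drug_id,
                        disease_id) -> PairFeatureMatrix:
    i = net.drug_pos(drug_id)
    j = net.disease_pos(disease_id)
    F = np.vstack([
        np.concatenate([net.R.values[i], net.A[i]]),
        np.concatenate([net.A[:, j], net.D.values[j]]),
    ])
    return PairFeatureMatrix(drug_id=drug_id, disease_id=disease_id, F=F)


def _global_weight_matrix(net: HeterogeneousNetwork,
                          excluded: set) -> np.ndarray:
    """(Nr+Nd)² edge-weight matrix for traversal: zero diagonal blocks'
    self-loops, with `excluded` (drug_idx, disease_idx) association edges
    removed."""
    nr = net.n_drugs
    A = net.A.copy()
    for i, j in excluded:
        A[i, j] = 0.0
    R = net.R.values.copy()
    D = net.D.values.copy()
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(D, 0.0)
    return np.block([[R, A], [A.T, D]])


def enumerate_paths(net: HeterogeneousNetwork, source_drug, target_disease,
                    max_len: int = 2, max_paths: int = 64,
                    leakage_mask=None) -> PathSet:
    """All simple paths of at most `max_len` edges from a drug to a disease.

    The direct (source, target) association edge is always excluded, as is
    every (drug_id, disease_id) pair in `leakage_mask`; the query pair
    therefore never sees its own label. If more than `max_paths` paths
    exist, those with the largest edge-weight products are kept.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1 edge")
    s = net.drug_pos(source_drug)
    t = net.disease_pos(target_disease)
    nr = net.n_drugs
    excluded = {(s, t)}
    if leakage_mask:
        for dr, ds in leakage_mask:
            i = dr if isinstance(dr, (int, np.integer)) else net.drug_pos(dr)
            j = ds if isinstance(ds, (int, np.integer)) else net.disease_pos(ds)
            excluded.add((i, j))

    t_global = nr + t
    found = []  # (index_tuple, weight)

    if max_len <= 2:
        # fast closed-form: the only shapes are s-r-t and s-d-t
        A = net.A
        r_ok = (net.R.values[s] > 0) & (A[:, t] > 0)
        r_ok[s] = False
        for r in np.nonzero(r_ok)[0]:
            if (r, t) in excluded:
                continue
            found.append(((s, int(r), t_global),
                          net.R.values[s, r] * A[r, t]))
        d_ok = (A[s] > 0) & (net.D.values[:, t] > 0)
        d_ok[t] = False
        for d in np.nonzero(d_ok)[0]:
            if (s, d) in excluded:
                continue
            found.append(((s, nr + int(d), t_global),
                          A[s, d] * net.D.values[d, t]))
    else:
        W = _global_weight_matrix(net, excluded)
        neighbors = [np.nonzero(W[v])[0] for v in range(W.shape[0])]

        def dfs(v, path, weight):
            if len(path) - 1 > max_len:
                return
            if v == t_global and len(path) > 1:
                found.append((tuple(path), weight))
                return
            if len(path) - 1 == max_len:
                return
            for u in neighbors[v]:
                if u not in path:
                    dfs(int(u), path + [int(u)], weight * W[v, u])

        dfs(s, [s], 1.0)
        # max_len > 2 still forbids the masked direct edge, but a 1-edge
        # path cannot occur because (s, t) is always excluded from W

    ids = net.drug_ids + net.disease_ids
    found.sort(key=lambda pw: (-pw[1], tuple(ids[v] for v in pw[0])))
    found = found[:max_paths]
    return PathSet(
        source=source_drug, target=target_disease,
        paths=[tuple(ids[v] for v in p) for p, _ in found],
        index_paths=[np.asarray(p) for p, _ in found],
        weights=np.asarray([w for _, w in found]),
    )


def embed_path(net: HeterogeneousNetwork, path) -> np.ndarray:
    """Embed a node-ID (or global-index) sequence as an (L, Nr+Nd) array."""
    E = embedding_matrix(net)
    idx = []
    for v in path:
        if isinstance(v, (int, np.integer)):
            idx.append(int(v))
        elif v in net._drug_pos:
            idx.append(net.drug_pos(v))
        else:
            idx.append(net.n_drugs + net.disease_pos(v))
    return E[np.asarray(idx)]
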