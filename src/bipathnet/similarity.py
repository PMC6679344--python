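"""Similarity layers of the heterogeneous drug-disease network.

Drug-drug similarity is the cosine of binary chemical-substructure
fingerprints. Disease-disease similarity can either be supplied
precomputed (the usual route when a MeSH-derived matrix already exists)
or computed here from per-disease term DAGs with the decay-weighted
shared-ancestor measure of the Wang family: each ancestor term t of a
disease d contributes C_d(t) = decay^depth (1 at d's own term), the
semantic value of d is the sum of contributions, and

    sim(d1, d2) = sum_{t shared} (C_d1(t) + C_d2(t)) / (SV(d1) + SV(d2)).

The three layers — drug similarities R, disease similarities D, and the
binary association matrix A — are assembled into one heterogeneous
network whose edges carry the matrix entries; any strictly positive
similarity is an edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import networkx as nx

from .data_io import ValidationError

log = logging.getLogger(__name__)

__all__ = ["SimilarityMatrix", "DiseaseDag", "HeterogeneousNetwork",
           "cosine_similarity", "semantic_similarity", "build_network",
           "read_disease_dags"]


@dataclass
class SimilarityMatrix:
    """Symmetric [0,1] similarity matrix with its entity-ID index."""
    ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"similarity shape {self.values.shape} != ({n}, {n})")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValidationError("similarity entries outside [0, 1]")
        if np.abs(self.values - self.values.T).max() > 1e-8:
            raise ValidationError("similarity matrix not symmetric")


@dataclass
class DiseaseDag:
    """Rooted term DAG for one disease: directed parent -> child edges.

    The disease's own MeSH term is the (unique) sink reached from the
    root; ancestors contribute to the semantic value with geometric decay.
    """
    disease_id: str
    edges: list  # [(parent_term, child_term)]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_node(self.disease_id)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError(
                f"term graph of {self.disease_id} contains a cycle")
        return g


def cosine_similarity(fp) -> SimilarityMatrix:
    """Pairwise cosine similarity of fingerprint rows: R_ij = ci·cj/(|ci||cj|).

    All-zero rows get similarity 0 to every other drug (and 1 on the
    diagonal, which is forced to 1 for every drug).
    """
    X = fp.bits.astype(float)
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        log.warning("drugs with all-zero fingerprints get similarity 0: %s",
                    [d for d, z in zip(fp.drug_ids, zero) if z])
    safe = np.where(zero, 1.0, norms)
    R = (X @ X.T) / np.outer(safe, safe)
    R[zero, :] = 0.0
    R[:, zero] = 0.0
    np.clip(R, 0.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    R = (R + R.T) / 2.0
    return SimilarityMatrix(ids=list(fp.drug_ids), values=R)


def _contributions(dag: DiseaseDag, decay: float) -> dict:
    """C_d(t) for every term t in the DAG of disease d.

    The disease's own term scores 1; any other term scores
    max over its children c of decay * C_d(c).
    """
    g = dag.graph()
    C = {dag.disease_id: 1.0}
    for t in reversed(list(nx.topological_sort(g))):
        if t == dag.disease_id:
            continue
        kids = [C[c] for c in g.successors(t) if c in C]
        C[t] = decay * max(kids) if kids else 0.0
    # terms not on a path to the disease term contribute nothing
    return {t: v for t, v in C.items() if v > 0}


def semantic_similarity(dags: dict, decay: float = 0.5) -> SimilarityMatrix:
    """Decay-weighted shared-term similarity over disease term DAGs."""
    if not 0.0 < decay < 1.0:
        raise ValidationError("decay must be in (0, 1)")
    ids = list(dags)
    contrib = {d: _contributions(dags[d], decay) for d in ids}
    sv = {d: sum(contrib[d].values()) for d in ids}
    n = len(ids)
    D = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = contrib[ids[i]], contrib[ids[j]]
            shared = ci.keys() & cj.keys()
            num = sum(ci[t] + cj[t] for t in shared)
            D[i, j] = D[j, i] = num / (sv[ids[i]] + sv[ids[j]])
    return SimilarityMatrix(ids=ids, values=D)


def read_disease_dags(path) -> dict:
    """Read per-disease term DAGs from a 3-column TSV
    (disease_id, parent_term, child_term)."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                     names=["disease_id", "parent", "child"])
    dags = {}
    for did, grp in df.groupby("disease_id", sort=False):
        dags[did] = DiseaseDag(disease_id=did,
                               edges=list(zip(grp["parent"], grp["child"])))
    return dags


class HeterogeneousNetwork:
    """Drugs + diseases with three weighted edge layers.

    Edge rule: any strictly positive off-diagonal similarity is an edge;
    associations are edges where A_ij = 1. Self-loops never appear in the
    adjacency views used for path traversal, although the stored R and D
    keep their unit diagonals (the node feature vectors use them).
    """

    def __init__(self, R: SimilarityMatrix, D: SimilarityMatrix,
                 A: np.ndarray):
        A = np.asarray(A, dtype=float)
        nr, nd = len(R.ids), len(D.ids)
        if A.shape != (nr, nd):
            raise ValidationError(
                f"association matrix shape {A.shape} != ({nr}, {nd})")
        if not np.isin(A, (0, 1)).all():
            raise ValidationError("association matrix must be binary")
        self.R, self.D, self.A = R, D, A
        self.drug_ids = list(R.ids)
        self.disease_ids = list(D.ids)
        self.n_drugs, self.n_diseases = nr, nd
        self._drug_pos = {d: i for i, d in enumerate(self.drug_ids)}
        self._disease_pos = {d: i for i, d in enumerate(self.disease_ids)}

    # adjacency views (recomputed cheaply; A may be masked per fold)
    @property
    def drug_adj(self) -> np.ndarray:
        """Boolean Nr×Nr drug-drug adjacency: R_ij > 0, no self-loops."""
        adj = self.R.values > 0
        np.fill_diagonal(adj, False)
        return adj

    @property
    def disease_adj(self) -> np.ndarray:
        adj = self.D.values > 0
        np.fill_diagonal(adj, False)
        return adj

    def drug_pos(self, drug_id) -> int:
        try:
            return self._drug_pos[drug_id]
        except KeyError:
            raise KeyError(f"unknown drug ID {drug_id!r}") from None

    def disease_pos(self, disease_id) -> int:
        try:
            return self._disease_pos[disease_id]
        except KeyError:
            raise KeyError(f"unknown disease ID {disease_id!r}") from None

    def masked(self, removed_pairs) -> "HeterogeneousNetwork":
        """Copy of the network with the given (drug_idx, disease_idx)
        association edges removed — used to hide test-fold labels."""
        A = self.A.copy()
        for i, j in removed_pairs:
            A[i, j] = 0.0
        return HeterogeneousNetwork(self.R, self.D, A)


def build_network(R: SimilarityMatrix, D: SimilarityMatrix,
                  A: np.ndarray) -> HeterogeneousNetwork:
    """Assemble the heterogeneous network from its three layers."""
    return HeterogeneousNetwork(R, D, A)
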