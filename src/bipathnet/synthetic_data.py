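"""Planted-block synthetic data emulating the structure the predictor
assumes: similar drugs share diseases and similar diseases share drugs.

Drugs are drawn from cluster prototype fingerprints with bit-flip noise,
so within-cluster cosine similarity exceeds between-cluster. Disease
similarity is a block matrix (high within a cluster, low between).
Each drug cluster is matched to one disease cluster; association edges
appear with probability density x enrichment inside matched blocks and
density elsewhere. Recovering these planted blocks from held-out edges
is the package's end-to-end test bed.

The real corpus this emulates (763 drugs x 681 diseases, 3051 known
associations, roughly one positive per 169 negatives) is not bundled.
The default config is a fast 50x40 world; `SyntheticConfig.acceptance()`
scales it to 200x150, and `plant_ratio` can thin either to the corpus's
1:169 imbalance when its sparsity — rather than its signal — is the
thing under study.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .data_io import (AssociationList, FingerprintTable, ValidationError,
                      write_associations, write_fingerprints,
                      write_similarity_matrix)
from .similarity import SimilarityMatrix

__all__ = ["SyntheticConfig", "generate", "plant_ratio",
           "neighbor_vote_scores", "write_dataset"]


@dataclass
class SyntheticConfig:
    n_drugs: int = 50
    n_diseases: int = 40
    fingerprint_width: int = 128
    n_drug_clusters: int = 5
    n_disease_clusters: int = 4
    bit_flip_noise: float = 0.1
    association_density: float = 0.002
    within_block_enrichment: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.bit_flip_noise <= 1
                and 0 <= self.association_density <= 1):
            raise ValidationError("probabilities must be in [0, 1]")
        if self.within_block_enrichment < 1:
            raise ValidationError("enrichment must be >= 1")

    @classmethod
    def acceptance(cls, seed: int = 0) -> "SyntheticConfig":
        """The 200x150 evaluation-scale world: default generative
        parameters with cluster counts scaled up. For the real corpus's
        ~1:169 sparsity apply plant_ratio(config, 169) on top."""
        return cls(n_drugs=200, n_diseases=150, fingerprint_width=128,
                   n_drug_clusters=10, n_disease_clusters=8, seed=seed)

    # cluster assignments are deterministic functions of the sizes
    def drug_clusters(self) -> np.ndarray:
        return np.arange(self.n_drugs) % self.n_drug_clusters

    def disease_clusters(self) -> np.ndarray:
        return np.arange(self.n_diseases) % self.n_disease_clusters

    def matched_disease_cluster(self, drug_cluster: int) -> int:
        return drug_cluster % self.n_disease_clusters

    def matched_fraction(self) -> float:
        dc = self.drug_clusters()
        sc = self.disease_clusters()
        m = 0
        for k in range(self.n_drug_clusters):
            m += (dc == k).sum() * (sc == self.matched_disease_cluster(k)).sum()
        return m / (self.n_drugs * self.n_diseases)


def plant_ratio(config: SyntheticConfig,
                target_ratio: float) -> SyntheticConfig:
    """Set the base density so that the expected negative:positive ratio
    of the generated association matrix equals `target_ratio`."""
    if target_ratio <= 1:
        raise ValidationError("target_ratio must exceed 1")
    rate = 1.0 / (1.0 + target_ratio)
    f = config.matched_fraction()
    density = rate / ((1 - f) + f * config.within_block_enrichment)
    if density > 1 or density * config.within_block_enrichment > 1:
        raise ValidationError(
            f"target ratio {target_ratio} infeasible: implied density "
            f"{density:.4g} with enrichment {config.within_block_enrichment}")
    return replace(config, association_density=density)


def generate(config: SyntheticConfig):
    """Sample one synthetic world.

    Returns (FingerprintTable, disease SimilarityMatrix, AssociationList,
    block_map) where block_map records the planted cluster assignments.
    """
    rng = np.random.default_rng(config.seed)
    nr, nd, w = config.n_drugs, config.n_diseases, config.fingerprint_width
    drug_ids = [f"r{i + 1}" for i in range(nr)]
    disease_ids = [f"d{j + 1}" for j in range(nd)]
    dcl = config.drug_clusters()
    scl = config.disease_clusters()

    # fingerprints: cluster prototypes with flip noise
    prototypes = rng.integers(0, 2, size=(config.n_drug_clusters, w))
    flips = rng.random((nr, w)) < config.bit_flip_noise
    bits = np.abs(prototypes[dcl] - flips.astype(int))
    fp = FingerprintTable(drug_ids=drug_ids, bits=bits.astype(np.int8))

    # disease similarity: block matrix, symmetric, unit diagonal
    D = np.zeros((nd, nd))
    for a in range(nd):
        for b in range(a + 1, nd):
            if scl[a] == scl[b]:
                D[a, b] = rng.uniform(0.6, 0.9)
            else:
                D[a, b] = rng.uniform(0.0, 0.3)
    D = D + D.T
    np.fill_diagonal(D, 1.0)
    dis_sim = SimilarityMatrix(ids=disease_ids, values=D)

    # associations: enriched inside matched (drug-cluster, disease-cluster)
    # blocks, base density elsewhere
    matched = np.zeros((nr, nd), dtype=bool)
    for k in range(config.n_drug_clusters):
        matched[np.ix_(dcl == k,
                       scl == config.matched_disease_cluster(k))] = True
    p = np.where(matched,
                 min(config.association_density
                     * config.within_block_enrichment, 1.0),
                 config.association_density)
    A = rng.random((nr, nd)) < p
    if not A.any():
        raise ValidationError(
            "configuration produced zero positive associations")
    pairs = [(drug_ids[i], disease_ids[j]) for i, j in zip(*np.nonzero(A))]
    assoc = AssociationList(pairs=pairs, drug_index=drug_ids,
                            disease_index=disease_ids)
    block_map = {"drug_cluster": dcl, "disease_cluster": scl,
                 "matched_block": matched}
    return fp, dis_sim, assoc, block_map


def neighbor_vote_scores(R: np.ndarray, D: np.ndarray,
                         A: np.ndarray) -> np.ndarray:
    """Similarity-weighted neighbour vote, the sanity baseline.

    score(i, j) averages (a) other drugs' associations with j weighted by
    their similarity to drug i and (b) disease j's similarity to the
    diseases of drug i. The pair's own edge never enters its score, so
    the baseline can be evaluated against A itself without leakage.
    """
    R = np.asarray(R, float).copy()
    D = np.asarray(D, float).copy()
    A = np.asarray(A, float)
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(D, 0.0)
    drug_vote = (R @ A) / np.maximum(R.sum(axis=1, keepdims=True), 1e-12)
    dis_vote = (A @ D) / np.maximum(D.sum(axis=0, keepdims=True), 1e-12)
    return (drug_vote + dis_vote) / 2.0


def write_dataset(config: SyntheticConfig, outdir):
    """Generate and write fingerprints.tsv, disease_similarity.tsv,
    associations.tsv and block_map.tsv under `outdir`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fp, dis_sim, assoc, block_map = generate(config)
    write_fingerprints(fp, outdir / "fingerprints.tsv")
    write_similarity_matrix(dis_sim, outdir / "disease_similarity.tsv")
    write_associations(assoc, outdir / "associations.tsv")
    import pandas as pd
    pd.DataFrame({
        "entity": fp.drug_ids + dis_sim.ids,
        "kind": ["drug"] * len(fp.drug_ids) + ["disease"] * len(dis_sim.ids),
        "cluster": np.concatenate([block_map["drug_cluster"],
                                   block_map["disease_cluster"]]),
    }).to_csv(outdir / "block_map.tsv", sep="\t", index=False)
    return fp, dis_sim, assoc, block_map
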