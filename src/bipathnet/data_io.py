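"""On-disk artifacts: fingerprints, similarity matrices, association lists,
predictions, and run configuration.

Everything is plain TSV with ID headers so that matrices at the scale of a
few hundred drugs and diseases stay human-inspectable. Entity order is
canonical: drugs follow the fingerprint file's row order, diseases follow
the similarity file's row order; the association file never defines an index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "FingerprintTable", "AssociationList", "RunConfig",
    "FormatError", "ValidationError", "ResolutionError",
    "read_fingerprints", "write_fingerprints",
    "read_similarity_matrix", "write_similarity_matrix",
    "read_associations", "write_associations",
    "write_predictions", "load_config",
]


class FormatError(ValueError):
    """File does not have the expected shape/layout."""


class ValidationError(ValueError):
    """File parsed but violates a domain invariant."""


class ResolutionError(KeyError):
    """An entity ID does not resolve against the canonical index."""


@dataclass
class FingerprintTable:
    """Binary chemical-substructure fingerprints, one row per drug.

    The classic PubChem substructure key set is 869 bits wide; any width
    is accepted. Rows with no set bit are kept but flagged degenerate —
    their cosine similarity to every other drug is defined as 0.
    """
    drug_ids: list
    bits: np.ndarray  # (Nr, W) of {0,1}

    def __post_init__(self):
        self.bits = np.asarray(self.bits)
        if len(self.drug_ids) != len(set(self.drug_ids)):
            raise ValidationError("duplicate drug IDs in fingerprint table")
        if not np.isin(self.bits, (0, 1)).all():
            raise FormatError("fingerprint entries must be 0 or 1")
        degenerate = [d for d, row in zip(self.drug_ids, self.bits)
                      if not row.any()]
        if degenerate:
            log.warning("all-zero fingerprint rows for: %s", degenerate)
        self.degenerate = degenerate

    @property
    def n_drugs(self):
        return len(self.drug_ids)

    @property
    def width(self):
        return self.bits.shape[1]


@dataclass
class AssociationList:
    """Known drug-disease association pairs and the implied binary matrix A."""
    pairs: list                 # [(drug_id, disease_id)]
    drug_index: list
    disease_index: list
    matrix: np.ndarray = field(init=False)

    def __post_init__(self):
        ri = {d: i for i, d in enumerate(self.drug_index)}
        di = {d: i for i, d in enumerate(self.disease_index)}
        A = np.zeros((len(self.drug_index), len(self.disease_index)))
        unique = {}
        for row, (dr, ds) in enumerate(self.pairs):
            if dr not in ri:
                raise ResolutionError(f"row {row}: unknown drug ID {dr!r}")
            if ds not in di:
                raise ResolutionError(f"row {row}: unknown disease ID {ds!r}")
            if (dr, ds) in unique:
                log.warning("duplicate association pair (%s, %s) ignored", dr, ds)
                continue
            unique[(dr, ds)] = None
            A[ri[dr], di[ds]] = 1.0
        self.pairs = list(unique)  # first-appearance order
        self.matrix = A


@dataclass
class RunConfig:
    """Hyperparameters of the full train/evaluate protocol.

    `combine_weight` is λ of the score combination s = λ·s_n + (1−λ)·s_p;
    0.12 favours the path branch, the value the source protocol settled on
    after tuning over {0.1, ..., 0.9}.
    """
    combine_weight: float = 0.12
    learning_rate: float = 1e-3
    pconv: int = 1
    conv1_kernel: tuple = (3, 5)
    conv1_channels: int = 16
    pool1_width: int = 2
    conv2_kernel: tuple = (3, 11)
    conv2_channels: int = 32
    pool2_width: int = 2
    lstm_hidden_size: int = 64
    max_path_len: int = 2          # edges per path
    max_paths_per_pair: int = 64
    epochs: int = 20
    batch_size: int = 64
    folds: int = 5
    repetitions: int = 20
    seed: int = 0
    conventional_lstm: bool = False
    recall_ks: tuple = (30, 60, 120)
    dtype: str = "float32"  # training/scoring precision; checks use float64

    def __post_init__(self):
        if not 0.0 <= self.combine_weight <= 1.0:
            raise ValidationError("combine_weight must be in [0, 1]")
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        for name in ("pool1_width", "pool2_width", "conv1_channels",
                     "conv2_channels"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        for k in ("conv1_kernel", "conv2_kernel", "recall_ks"):
            setattr(self, k, tuple(getattr(self, k)))
            if any(v < 1 for v in getattr(self, k)):
                raise ValidationError(f"{k} entries must be positive")

    def to_dict(self):
        d = asdict(self)
        d["conv1_kernel"] = list(self.conv1_kernel)
        d["conv2_kernel"] = list(self.conv2_kernel)
        d["recall_ks"] = list(self.recall_ks)
        return d


def load_config(path) -> RunConfig:
    """Read a RunConfig from YAML; unknown keys are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


# -- fingerprints -----------------------------------------------------------

def read_fingerprints(path) -> FingerprintTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        bad = vals[~np.isin(vals, (0, 1))][0]
        raise FormatError(f"non-binary fingerprint entry {bad!r} in {path}")
    return FingerprintTable(drug_ids=[str(i) for i in df.index],
                            bits=vals.astype(np.int8))


def write_fingerprints(table: FingerprintTable, path):
    df = pd.DataFrame(table.bits,
                      index=pd.Index(table.drug_ids, name="drug_id"),
                      columns=[f"bit{i}" for i in range(table.width)])
    df.to_csv(path, sep="\t")


# -- similarity matrices ----------------------------------------------------

def read_similarity_matrix(path):
    """Read a square similarity TSV into a (ids, values) SimilarityMatrix.

    Off-symmetric entries within 1e-8 are accepted silently; larger
    asymmetries are symmetrized by averaging with a warning. The diagonal
    is forced to 1.
    """
    from .similarity import SimilarityMatrix  # deferred: avoid cycle
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"similarity matrix in {path} is not square: {df.shape}")
    if [str(i) for i in df.index] != [str(c) for c in df.columns]:
        raise FormatError(f"row/column IDs disagree in {path}")
    vals = df.to_numpy(dtype=float)
    if ((vals < 0) | (vals > 1)).any():
        bad = vals[(vals < 0) | (vals > 1)][0]
        raise ValidationError(f"similarity entry {bad} outside [0, 1] in {path}")
    if np.abs(vals - vals.T).max() > 1e-8:
        warnings.warn(f"asymmetric similarity matrix in {path}; symmetrizing "
                      "by averaging")
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 1.0)
    return SimilarityMatrix(ids=[str(i) for i in df.index], values=vals)


def write_similarity_matrix(sim, path):
    pd.DataFrame(sim.values, index=pd.Index(sim.ids, name="id"),
                 columns=sim.ids).to_csv(path, sep="\t")


# -- associations -----------------------------------------------------------

def read_associations(path, drug_index, disease_index) -> AssociationList:
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                         names=["drug_id", "disease_id"])
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["drug_id", "disease_id"])
    pairs = list(df.itertuples(index=False, name=None))
    return AssociationList(pairs=pairs, drug_index=list(drug_index),
                           disease_index=list(disease_index))


def write_associations(assoc: AssociationList, path):
    with open(path, "w") as fh:
        for dr, ds in assoc.pairs:
            fh.write(f"{dr}\t{ds}\n")


def write_predictions(rows, path):
    """rows: iterable of (drug_id, disease_id, score, rank_within_drug)."""
    df = pd.DataFrame(rows, columns=["drug_id", "disease_id", "score",
                                     "rank_within_drug"])
    df.to_csv(path, sep="\t", index=False)
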