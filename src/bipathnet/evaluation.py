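"""Ranking evaluation: per-drug ROC/AUC, precision-recall/AUPR, top-k
recall, aggregation over repeated k-fold cross-validation, and a paired
signed-rank comparison of score sets.

Each drug is evaluated on its own candidate list (held-out positives
against the never-associated background); the model-level number is the
macro average over drugs. AUC uses the tie-aware rank (Mann-Whitney)
formulation; AUPR sums precision at each recalled positive's rank
(average precision, the step-wise interpolation of the P-R curve).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["RankedPredictions", "EvalResult", "rank_predictions", "roc_auc",
           "pr_auc", "recall_at_k", "aggregate_cv", "paired_rank_test"]


@dataclass
class RankedPredictions:
    """One drug's candidate diseases sorted by descending score; ties are
    broken by disease ID so rankings are reproducible."""
    drug_id: str
    disease_ids: list
    scores: np.ndarray
    labels: np.ndarray  # 1 = held-out known association

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        order = sorted(range(len(self.scores)),
                       key=lambda k: (-self.scores[k], self.disease_ids[k]))
        self.disease_ids = [self.disease_ids[k] for k in order]
        self.scores = self.scores[order]
        self.labels = self.labels[order]


def rank_predictions(drug_id, disease_ids, scores, labels) -> RankedPredictions:
    return RankedPredictions(drug_id, list(disease_ids), scores, labels)


def roc_auc(ranked: RankedPredictions) -> float:
    """Tie-aware AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    y, s = ranked.labels, ranked.scores
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"drug {ranked.drug_id}: AUC needs both classes")
    r = stats.rankdata(s)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def pr_auc(ranked: RankedPredictions) -> float:
    """Average precision over the (tie-broken) ranking: mean of precision
    at each positive's rank."""
    y = ranked.labels
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError(f"drug {ranked.drug_id}: AUPR needs a positive")
    ranks = np.arange(1, len(y) + 1)
    cum_tp = np.cumsum(y)
    precision_at_pos = (cum_tp / ranks)[y == 1]
    return float(precision_at_pos.mean())


def recall_at_k(ranked: RankedPredictions, k: int) -> float:
    if k < 1:
        raise ValueError("k must be >= 1")
    n_pos = int(ranked.labels.sum())
    if n_pos == 0:
        raise ValueError(f"drug {ranked.drug_id}: recall needs a positive")
    return float(ranked.labels[:k].sum() / n_pos)


@dataclass
class EvalResult:
    """Per (drug, repetition, fold) metric rows plus macro averages."""
    rows: pd.DataFrame
    macro: dict = field(init=False)

    def __post_init__(self):
        metrics = [c for c in self.rows.columns
                   if c not in ("drug_id", "repetition", "fold")]
        # mean over folds/repetitions per drug, then across drugs
        per_drug = self.rows.groupby("drug_id")[metrics].mean()
        self.macro = per_drug.mean().to_dict()
        self.per_drug = per_drug


def aggregate_cv(per_fold_rows, repetitions: int | None = None) -> EvalResult:
    """Combine per-fold evaluation rows into per-drug and macro averages.

    `per_fold_rows`: iterable of dicts with keys drug_id, repetition, fold
    and one entry per metric. Every repetition must contribute the full
    set of folds.
    """
    df = pd.DataFrame(list(per_fold_rows))
    if df.empty:
        raise ValueError("no evaluation rows to aggregate")
    counts = df.groupby("repetition")["fold"].nunique()
    if counts.nunique() > 1:
        raise ValueError(f"missing folds in some repetitions: "
                         f"{counts.to_dict()}")
    if repetitions is not None and len(counts) != repetitions:
        raise ValueError(f"expected {repetitions} repetitions, "
                         f"got {len(counts)}")
    return EvalResult(rows=df)


def paired_rank_test(per_drug_metric_a, per_drug_metric_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-drug metrics.

    Zero differences are dropped; if every difference is zero the methods
    are indistinguishable and p = 1 is returned with a warning.
    """
    a = np.asarray(per_drug_metric_a, dtype=float)
    b = np.asarray(per_drug_metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be paired 1-D vectors")
    if len(a) < 6:
        raise ValueError("signed-rank test needs at least 6 pairs")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; returning p = 1")
        return 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                         method="auto")
    return float(res.pvalue)
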