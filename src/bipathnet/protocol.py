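"""End-to-end protocol: repeated k-fold cross-validation with balanced
negative sampling, per-drug ranking evaluation, whole-matrix prediction,
and model checkpointing.

Per repetition, a fresh negative sample (one never-associated pair per
known association) is drawn and both classes are split into k folds.
Each fold's model trains on the other folds with the held-out positive
edges removed from the network (so no path or feature can see a test
label) and is evaluated per drug: every drug with a held-out positive is
ranked over its held-out positives plus the never-associated background.
Training-fold positives are neither positives nor negatives at
evaluation time — they are simply absent from the candidate list.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_io import RunConfig
from .evaluation import (EvalResult, aggregate_cv, pr_auc, rank_predictions,
                         recall_at_k, roc_auc)
from .features import embedding_matrix
from .similarity import HeterogeneousNetwork
from .training import (ModelState, init_model, make_folds, sample_negatives,
                       score_pairs, train)

log = logging.getLogger(__name__)

__all__ = ["run_full_protocol", "predict", "save_model", "load_model",
           "write_manifest"]


def _combine(s_n, s_p, lam):
    s = lam * s_n + (1 - lam) * s_p
    return np.where(np.isnan(s_p), s_n, s)


def evaluate_fold(state: ModelState, net_fold: HeterogeneousNetwork,
                  A_full: np.ndarray, test_pos, config: RunConfig,
                  E=None):
    """Per-drug ranking metrics for one trained fold.

    Returns a list of dicts (one per drug holding a test positive) with
    the combined-score metrics plus CNN-only / path-only AUC ablations.
    """
    by_drug = {}
    for i, j in test_pos:
        by_drug.setdefault(i, []).append(j)
    if E is None:
        E = embedding_matrix(net_fold)
    rows = []
    for i, test_js in sorted(by_drug.items()):
        neg_js = [int(j) for j in np.nonzero(A_full[i] == 0)[0]]
        cand = sorted(set(test_js) | set(neg_js))
        labels = np.asarray([1 if j in set(test_js) else 0 for j in cand])
        raw = score_pairs(state, net_fold, [(i, j) for j in cand], config,
                          E=E)
        s_n, s_p = raw[:, 0], raw[:, 1]
        dids = [net_fold.disease_ids[j] for j in cand]
        drug_id = net_fold.drug_ids[i]
        row = {"drug_id": drug_id}
        ranked = rank_predictions(drug_id, dids,
                                  _combine(s_n, s_p, config.combine_weight),
                                  labels)
        row["auc"] = roc_auc(ranked)
        row["aupr"] = pr_auc(ranked)
        for k in config.recall_ks:
            row[f"recall@{k}"] = recall_at_k(ranked, k)
        row["auc_cnn"] = roc_auc(rank_predictions(
            drug_id, dids, _combine(s_n, s_p, 1.0), labels))
        row["auc_path"] = roc_auc(rank_predictions(
            drug_id, dids, _combine(s_n, s_p, 0.0), labels))
        rows.append(row)
    return rows


def run_full_protocol(net: HeterogeneousNetwork, config: RunConfig,
                      repetitions: int | None = None,
                      shuffle_labels: bool = False,
                      out_dir=None) -> EvalResult:
    """Repeat (negative sampling -> k-fold split -> train -> evaluate).

    `shuffle_labels` permutes the training labels within each fold (the
    no-signal control); evaluation labels stay truthful. Writes
    metrics.tsv, loss_history.tsv and a manifest when `out_dir` is given.
    """
    reps = config.repetitions if repetitions is None else repetitions
    pos_pairs = [(int(i), int(j)) for i, j in zip(*np.nonzero(net.A))]
    rows, loss_rows = [], []
    for rep in range(reps):
        rng = np.random.default_rng([config.seed, rep])
        negatives = sample_negatives(net.A, len(pos_pairs), rng)
        tset = make_folds(pos_pairs, negatives, config.folds, rng)
        for fold in range(config.folds):
            train_pairs, labels, test_pos = tset.fold_split(fold)
            if shuffle_labels:
                labels = labels[rng.permutation(len(labels))]
            net_fold = net.masked(test_pos)
            state, history = train(net_fold, train_pairs, labels, config,
                                   rng)
            for ep, (ln, lp, tot) in enumerate(history):
                loss_rows.append({"repetition": rep, "fold": fold,
                                  "epoch": ep, "loss_n": ln, "loss_p": lp,
                                  "total": tot})
            for row in evaluate_fold(state, net_fold, net.A, test_pos,
                                     config):
                row.update({"repetition": rep, "fold": fold})
                rows.append(row)
            log.info("rep %d fold %d: %d drugs evaluated", rep, fold,
                     len({r['drug_id'] for r in rows}))
    result = aggregate_cv(rows, repetitions=reps)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.rows.to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
        pd.DataFrame(loss_rows).to_csv(out_dir / "loss_history.tsv",
                                       sep="\t", index=False)
        write_manifest(out_dir, command="run-cv", config=config,
                       outputs=["metrics.tsv", "loss_history.tsv"])
    result.loss_history = pd.DataFrame(loss_rows)
    return result


def predict(state: ModelState, net: HeterogeneousNetwork, config: RunConfig,
            pairs=None) -> pd.DataFrame:
    """Score pairs (default: every unknown pair) and rank within drug.

    Returns a DataFrame (drug_id, disease_id, score, rank_within_drug);
    ranks count down from 1 = best per drug, ties broken by disease ID.
    """
    if pairs is None:
        pairs = [(int(i), int(j)) for i, j in zip(*np.nonzero(net.A == 0))]
    else:
        pairs = [(net.drug_pos(a) if isinstance(a, str) else int(a),
                  net.disease_pos(b) if isinstance(b, str) else int(b))
                 for a, b in pairs]
    raw = score_pairs(state, net, pairs, config)
    s = _combine(raw[:, 0], raw[:, 1], config.combine_weight)
    df = pd.DataFrame({
        "drug_id": [net.drug_ids[i] for i, _ in pairs],
        "disease_id": [net.disease_ids[j] for _, j in pairs],
        "score": s,
    })
    df["rank_within_drug"] = (
        df.sort_values(["score", "disease_id"], ascending=[False, True])
          .groupby("drug_id").cumcount() + 1)
    df = df.sort_values(["drug_id", "rank_within_drug"]).reset_index(drop=True)
    return df


# -- checkpointing ----------------------------------------------------------

def save_model(state: ModelState, config: RunConfig, n_features: int,
               model_dir):
    """Flat archive of named parameter tensors plus a config snapshot."""
    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    np.savez(model_dir / "parameters.npz",
             **{k: t.data for k, t in state.tensors().items()})
    meta = {"config": config.to_dict(), "n_features": int(n_features)}
    (model_dir / "model.yaml").write_text(yaml.safe_dump(meta))


def load_model(model_dir):
    """Rebuild (state, config, n_features) from a save_model directory."""
    model_dir = Path(model_dir)
    meta_path = model_dir / "model.yaml"
    if not meta_path.exists():
        raise FileNotFoundError(
            f"{model_dir} is not a trained model directory "
            "(missing model.yaml)")
    meta = yaml.safe_load(meta_path.read_text())
    config = RunConfig(**meta["config"])
    n_features = meta["n_features"]
    state = init_model(n_features, config, np.random.default_rng(0))
    with np.load(model_dir / "parameters.npz") as arrs:
        for k, t in state.tensors().items():
            t.data = np.asarray(arrs[k], dtype=float)
    return state, config, n_features


def write_manifest(out_dir, command: str, config: RunConfig,
                   outputs, inputs=None):
    """Atomic JSON run manifest: command, config, seed, input digests."""
    out_dir = Path(out_dir)
    digests = {}
    for p in inputs or []:
        p = Path(p)
        digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "command": command,
        "config": config.to_dict(),
        "seed": config.seed,
        "input_digests": digests,
        "outputs": list(outputs),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    tmp = out_dir / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2))
    tmp.replace(out_dir / "manifest.json")
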