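# bipathnet

Drug repositioning by link prediction on a heterogeneous drug–disease
network. Given binary chemical-substructure fingerprints, a
disease–disease semantic similarity matrix (or MeSH-style term DAGs to
compute one), and a list of known drug–disease associations, the package
trains a two-branch neural scorer and ranks every drug's candidate
diseases — the standard triage step before wet-lab or database
validation of repositioning hypotheses.

## Model

The network has drug nodes and disease nodes with three weighted edge
layers: drug similarity **R** (cosine of fingerprints,
R_ij = c_i·c_j / (‖c_i‖‖c_j‖)), disease similarity **D**, and binary
associations **A**. A pair (r_i, d_j) is scored by two branches:

* a **CNN** over the spliced 2×(N_r+N_d) feature matrix
  F = [R_i ⊕ A_i· ; A_·j ⊕ D_j·] (pad → conv → average-pool → conv →
  average-pool → flatten → softmax head), capturing the pair's direct
  neighbourhood profile;
* a **BiLSTM with path-level attention** over all bounded-length simple
  paths r_i → … → d_j in the network, capturing multi-hop topology:
  each path's node-embedding sequence is encoded forward and backward,
  h = h_l^f ⊕ h_l^b, and attention weights α = softmax(u_i·u_p) fuse the
  paths into a single representation → softmax head.

The final association score is s = λ·s_n + (1−λ)·s_p with λ = 0.12;
both cross-entropies are minimized jointly with Adam. Held-out test
edges and each query pair's own edge are masked before path enumeration
and feature construction, so labels never leak into features. See
`docs/methods.md` for assumptions, parameter defaults, and limitations.

No deep-learning framework is required: the model runs on a small
NumPy autodiff tape shipped with the package (the cell update is
non-standard — see the methods note).

## Worked example

Everything is runnable without downloads via the planted-block synthetic
generator (similar drugs share diseases, similar diseases share drugs):

```sh
bipathnet simulate --seed 3 --out data/
bipathnet run-cv --data data/ --seed 1 --repetitions 2 --out results/
```

or equivalently through the library; the acceptance script does exactly
this end to end:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

prints (stderr):

```
synthetic world: 50 drugs x 40 diseases, 103 associations
auc: 0.6035
aupr: 0.1682
recall@30: 0.8345
recall@60: 1.0000
recall@120: 1.0000
auc_cnn: 0.6791
auc_path: 0.5913
elapsed: 25.7s
```

Reading: on this small 50×40 world with 103 known associations, repeated
5-fold cross-validation ranks each drug's held-out diseases against its
never-associated background. `auc` is the macro (per-drug) area under
the ROC curve of the combined score, `aupr` the macro average precision,
and `recall@k` the fraction of a drug's held-out diseases ranked in its
top k. `auc_cnn` / `auc_path` are single-branch ablations (λ = 1 and
λ = 0). Small worlds are data-limited; on the 200×150 world exercised by
`tests/test_acceptance.py` the combined macro AUC exceeds 0.85.

File formats are plain TSV throughout (`fingerprints.tsv` with a drug-ID
column and bit columns; square `disease_similarity.tsv` with matching
row/column IDs; two-column `associations.tsv`), and `predict` writes
`(drug_id, disease_id, score, rank_within_drug)`.

## Acceptance script

`scripts/acceptance.py --seed <int> --out <path>` regenerates the
synthetic world from the seed, reruns the full cross-validated protocol
(train + per-drug ranking evaluation), prints the macro metrics, and
writes the results JSON to `--out`.
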