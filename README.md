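# synergraph

Predicting whether a pair of anticancer drugs acts **synergistically or
antagonistically** in a given cancer cell line, using nothing but the
topology of a protein–protein interaction (PPI) network and the target
proteins of the drugs and cell lines — no chemical descriptors, no genomic
profiles.

## Who this is for

Computational biologists and ML researchers working on drug-combination
screening who want a network-medicine baseline: a pipeline that turns a PPI
edge list plus drug→protein and cell-line→protein association tables into a
cross-validated synergy classifier.

## The method

1. **Structural node embedding.** Every protein u gets a latent vector that
   encodes its *structural role* in the PPI network (not its neighborhood
   identity). For each hop distance k, compare the ascending degree sequence
   of u's ring R_k(u) with that of every other node by dynamic time warping
   under the element cost g(x, y) = max(x, y)/min(x, y) − 1, and accumulate

       f_k(u, v) = f_{k−1}(u, v) + DTW(s(R_k(u)), s(R_k(v))),   f_{−1} = 0.

   These distances define a multilayer graph — intra-layer weights
   w_k(u,v) = e^{−f_k(u,v)}, inter-layer weights log(Γ_k(u) + e) upward and 1
   downward — on which a biased random walk (stay probability q = 0.3, 20
   walks of 80 tokens per node, 4 layers) generates sentences for a
   Skip-Gram model with negative sampling (window 5, d = 64 by default).

2. **Entity features.** A drug (or cell line) is the arithmetic mean of its
   target-protein vectors: D_i = (P_1 + … + P_n)/n. A sample is the 3·d
   concatenation [drug A | drug B | cell line], 192-dimensional at d = 64.

3. **Classification.** Gradient-boosted trees (XGBoost `gbtree`, max_depth 7,
   learning_rate 0.1, subsample/colsample 0.9, gamma 0.1) classify samples
   labelled by the sign of the measured synergy score (Loewe/ZIP scale:
   score > 0 → 1, score < 0 → 0, exact zeros dropped). Performance is
   reported as ACC, recall, precision, F1, AUC-ROC and AUC-PR under repeated
   stratified five-fold cross-validation, with per-cell-line and per-tissue
   AUCs pooled over out-of-fold predictions.

A fully deterministic synthetic-study generator (`synergraph.synthetic`)
builds bridged-motif networks with planted structural roles and synergy
labels whose signal is carried *only* by those roles, so the whole pipeline
is testable end to end without any external downloads.

## Worked example

```python
import synergraph as sg

study = sg.make_synergy_study(n_drugs=10, n_cells=4, n_records=400, seed=1,
                              n_motifs=6, motif_size=6)
print("records:", len(study.records), " positive fraction:", round(study.positive_fraction, 3))
cvres, emb, table = sg.run_study(study, dim=32, folds=5, repeats=1, epochs=3)
print(cvres.summary.round(3))
print(sg.stratified_performance(cvres, by="tissue").round(3).to_string(index=False))
```

prints

```
records: 400  positive fraction: 0.505
            mean     sd
acc        0.888  0.038
recall     0.876  0.031
precision  0.901  0.066
f1         0.888  0.037
auc_roc    0.940  0.025
auc_pr     0.949  0.026
tissue  n_records  n_pos  n_neg  auc_roc
breast         90     21     69    0.895
 colon         92     70     22    0.918
  lung        100     60     40    0.892
  skin        118     51     67    0.958
```

The study plants a role-overlap signal with effect size 1 against Gaussian
noise (σ = 0.5), so an oracle that knew the latent score would top out around
AUC 0.9–0.95; the pipeline recovering ~0.94 on this small study means the
embeddings have captured the planted structural roles almost completely.
`stratified_performance` breaks the same out-of-fold predictions down by cell
line or tissue.

The same pipeline is available from the shell, driven by one YAML config:

```bash
synergraph run-all -c run.yaml     # simulate → embed → featurize → train → evaluate
```

where `run.yaml` names the four input files (or a `simulate:` section to
generate them) plus embedding, XGBoost and CV settings. Each stage writes its
artifact and a JSON manifest (inputs with checksums, parameters, seed,
version) into the output directory.

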