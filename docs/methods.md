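# Methods

## Problem setting

The package classifies drug–drug–cell-line triples as synergistic (label 1,
synergy score > 0) or antagonistic (label 0, score < 0). Zero scores are
excluded: the sign convention defines no class for them. The only inputs are
an undirected simple PPI network and the sets of proteins each drug and cell
line acts on; the model's premise is that two proteins with the same *local
network structure* should carry the same latent information, so features are
built from structural node embeddings rather than chemical or genomic
descriptors.

## Structural distances

For node u and hop distance k, R_k(u) is the set of nodes at exactly k hops
and s(R_k(u)) its ascending degree sequence. The layer-k distance
accumulates DTW costs between ring sequences:

    f_k(u,v) = f_{k−1}(u,v) + DTW(s(R_k(u)), s(R_k(v))),   f_{−1} = 0,

with element cost g(x,y) = max(x,y)/min(x,y) − 1. Properties relied on
throughout (and property-tested): f_k is symmetric, non-negative,
non-decreasing in k, and zero at every k for automorphically equivalent
pairs. The DTW is the exact full dynamic program — no window, no sequence
compression; ring sequences at desk scale are short, and the inner loop is
numba-compiled. Degrees must be ≥ 1, which is why isolated nodes are removed
at load time.

Rings are contiguous in k, so once a node's ring empties (k exceeds its
eccentricity) it stays empty; a pair exists in layer k only while both rings
are non-empty, and the per-layer pair set shrinks monotonically.

### Layer count

The layer cap defaults to k_max = 4, configurable. Using the full network
diameter instead is supported (pass a larger `k_max`) but rarely changes the
embedding: rings beyond a few hops cover most of a small-world graph and add
nearly identical DTW increments for all pairs.

Each layer is a **complete** weighted graph over the retained pairs. An
optional `max_degree_ratio` switch restricts comparisons to pairs of similar
degree for large graphs; it is an approximation and is off by default.

## Multilayer graph and walks

Intra-layer weight: w_k(u,v) = exp(−f_k(u,v)) ∈ (0,1], equal to 1 iff
f_k = 0. Inter-layer weights per node: upward log(Γ_k(u) + e) ≥ 1, where
Γ_k(u) counts u's intra-layer edges heavier than the layer's mean edge
weight, and downward constant 1.

The biased walk starts every walk at layer 0. Each step: with probability
q = 0.3 move within the layer — to v with probability exp(−f_k(u,v))/Z_k(u),
Z_k(u) = Σ_{v≠u} exp(−f_k(u,v)) — and **emit** the node landed on; with
probability 1 − q switch layers (up/down proportional to the inter-layer
weights; layer 0 forces up, the node's top layer forces down) and emit
nothing. `walk_length` (default 80) counts emitted tokens, the start node
being the first. This emission convention — switches consume a loop step but
no token — is a design choice the walk tests pin down explicitly. A node
with no same-layer partners forces a downward switch; layer 0 is complete
over all nodes, so the walk can never deadlock. q is not a quantity with an
external reference value; 0.3 is the conventional default for this family of
embeddings and is exposed as a parameter.

Defaults: 20 walks per node, length 80, 4 layers, window 5, dimension 64 —
the standard operating point for this embedding on PPI networks. Walk
generation derives one RNG substream per (seed, epoch, node index), so the
corpus is reproducible regardless of scheduling.

## Skip-Gram training

The trainer is an in-package implementation of Skip-Gram with negative
sampling: 5 negatives per positive pair drawn from the unigram distribution
raised to 3/4, fixed symmetric window (5), plain SGD with learning rate
decaying linearly 0.025 → 1e-4 over all epoch × pair updates, 5 epochs by
default. Logits are clipped to ±10 before the sigmoid for numerical safety.
No minimum-count filtering: every walked node must receive a vector because
downstream pooling indexes embeddings by target protein. Training is
single-threaded and consumes randomness only from the seeded generator, so
retraining with the same seed reproduces vectors **bit-identically** (the
stronger of the two reproducibility guarantees, and the one the tests
assert). Epochs, learning rate and the sampling scheme have no external
reference setting; the values above are the package's own defaults.

Supported dimensions are 32, 64 and 128; held-out AUC is empirically flat
across them (the dimension-robustness test bounds the spread at 0.05).

## Features and ordering symmetry

Entity features are exact arithmetic means of target-protein vectors; rows
are [drug A | drug B | cell] concatenations of width 3·d. Synergy is
order-free but concatenation is not, so training uses both orderings of each
record and prediction averages the model's scores for the two orderings.
Symmetrization happens *after* fold splitting (both copies of a record stay
on one side), and duplicated triples with conflicting measured signs are
kept with a warning — both choices are deliberate: the first prevents
leakage, the second reflects that conflicting repeat measurements are
information about label noise, not errors.

## Classifier and evaluation

XGBoost `gbtree` with max_depth 7, min_child_weight 1, gamma 0.1,
subsample 0.9, colsample_bytree 0.9, learning_rate 0.1, trained
single-threaded from a seed. The tree count is not part of the published
operating point; the default is 100 rounds and it is grid-searchable
(`grid_search` scores configurations by nested-CV mean AUC-ROC, breaking
ties toward the shallower, slower-learning model).

Cross-validation is stratified at the record level (class ratios preserved
within ±1 record per fold), `folds` × `repeats` with fresh seeded splits per
repeat; drugs and cell lines recur across train/test, matching the
record-level protocol. "Repeating the experiment five times" is implemented
as 5 independent repeats of 5-fold CV (both knobs are configurable, so the
alternative reading — the five folds themselves — is `repeats=1`).
Thresholded metrics (ACC, recall, precision, F1; threshold 0.5) come from
the confusion matrix; AUC-ROC is the trapezoidal area under the ROC curve
and AUC-PR is average precision. Out-of-fold scores are kept per record and
repeat; stratified summaries pool them per cell line or tissue and report
single-class groups as undefined (NaN) rather than dropping them.

## Synthetic studies

The generator emulates the four input files with planted, recoverable
structure:

* **Network**: `n_motifs` copies of one random connected motif (random
  spanning tree + extra edges), sparsely bridged (each motif pair bridged
  with probability `bridge_prob`; redrawn until connected, bounded retries).
  Corresponding motif positions form structural **roles** — the signal
  carrier. Bridges break exact automorphy slightly, which is realistic: real
  role equivalence in PPI networks is also approximate.
* **Targets**: each drug (4 targets) and cell line (10 targets) draws a
  Dirichlet(0.2) preference over roles and samples target proteins
  accordingly — sparse, role-concentrated target sets.
* **Labels**: the role-overlap statistic of a triple is the mean dot product
  of each drug's role histogram with the cell line's, z-standardised over
  the sampled records. The latent score is effect · s_cell · z + N(0, noise)
  with defaults effect 1, noise 0.5, and per-cell-line signal strengths
  s_cell (default 1; setting one to 0 creates a cell line whose labels are
  pure noise, used to validate the stratified summaries). The overlap
  statistic is right-skewed, so the generator solves for the centring offset
  that makes the *expected* positive fraction exactly 1/2 under the noise
  model — the planted class balance is a design target of the study, not an
  accident of the draw.

Default study size: 20 drugs × 8 cell lines × 2000 records on a 120-node,
12-motif network — large enough for stable five-fold estimates, small enough
that the full pipeline runs in about a minute on one core. At these settings
the latent signal-to-noise ratio puts an oracle that knows z at roughly
AUC 0.9, so the pipeline's ≈0.88 means near-complete recovery of the planted
roles. Randomness is ordered so that the network, targets, triples and noise
draws depend only on the seed — `effect` only rescales the latent score —
making studies at different effect sizes directly comparable (the
monotonicity test exploits this).

What the generator does **not** emulate: dose–response surfaces and real
Loewe/ZIP score computation, hub-dominated degree distributions of real PPI
networks, correlated target sets of drug families, or measurement batch
effects. Passing tests therefore demonstrate that the machinery recovers
structural-role signal when it exists; they do not certify performance on
real screens.

## Numerical choices and degenerate inputs

* DTW requires non-empty sequences of degrees ≥ 1; violations raise.
* Within-layer sampling uses cumulative-probability inversion with a final
  index clamp against floating-point 1.0 edge cases.
* Γ = 0 gives the upward-weight floor log(e) = 1, so upward switches are
  never impossible below the top layer.
* Single-class inputs: training raises; AUCs raise in `evaluate`; per-group
  AUCs become NaN in stratified summaries.
* Embedding text I/O round-trips at 10 significant digits.
* Exact-zero synergy scores are dropped at read time and counted.

## Known limitations

All-pairs structural distances are quadratic in node count; the optional
degree-ratio pruning trades exactness for scale but is off by default, so
the intended regime is networks up to a few thousand nodes. The Skip-Gram
trainer is CPU-only and single-threaded by design (reproducibility over
speed). Leave-cell-lines-out evaluation is available as an explicitly
labelled extra mode (`cross_validate(..., split_by="cell")`, grouped rather
than stratified splits), but record-level CV remains the supported protocol.
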