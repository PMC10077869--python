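# Methods

## Problem and pipeline

`fcgnn` classifies subjects into two groups (e.g. depressed patients vs
healthy controls) from whole-brain functional connectivity. The
pipeline is:

1. **Functional connectivity.** Each subject's scan is reduced to mean
   BOLD time series for R atlas regions (R = 160 for the Dosenbach
   parcellation; any R ≥ 2 works). Every region pair is Pearson
   correlated and the correlation is variance-stabilised with the
   Fisher z-transform, z = arctanh(r), giving a symmetric R × R matrix
   with zero diagonal. |r| is clipped at 0.999999 before arctanh so
   degenerate (perfectly correlated) series stay finite; the diagonal
   is forced to zero because self-connectivity is uninformative and
   arctanh(1) diverges.
2. **Graph construction.** The dense matrix is sparsified with a
   k-nearest-neighbour rule: each node keeps edges to the k nodes with
   the largest |z| (ties broken toward the lower node index, so graph
   construction is platform-independent), and the directed selections
   are symmetrised by union — an edge exists if either endpoint
   selected it, so node degree is at least k and at most R − 1. Edge
   weights default to |z| so the adjacency is nonnegative for
   normalised propagation; signed connectivity is preserved in the
   node features, where node i carries its full FC row z[i, ·].
3. **Base classifiers.** Three graph neural networks operate on these
   graphs, each ending in global mean pooling and a fully connected
   layer producing two class logits:
   * GCN: three layers of act(D̃^(−1/2) Ã D̃^(−1/2) X W) with
     Ã = A + I, ReLU, dropout 0.3, hidden width 64. The weighted
     adjacency feeds the propagation.
   * GAT: three multi-head attention layers (8 heads), eLU, dropout
     0.5. Attention logits are leaky-ReLU (slope 0.2) scored and
     softmax-normalised over each node's in-neighbourhood;
     self-attention is always enabled so isolated nodes are well
     defined. Heads are concatenated on hidden layers (8 features per
     head × 8 heads = 64) and averaged on the last layer. GAT consumes
     the binary edge structure only.
   * GraphSAGE: K = 3 layers of act(W_self x_i + W_neigh · mean of
     neighbour features), hidden 64, ReLU, dropout 0.3; the mean over
     an empty neighbourhood is the zero vector. The sum of two
     transforms is the standard equivalent of concatenating self and
     neighbour channels before a single linear map.
4. **Stacking ensemble.** The three bases are trained independently on
   the same training fold with Adam (learning rate 0.01, weight decay
   5 × 10⁻⁴) on cross-entropy, then frozen. Their output features —
   pre-softmax logits by default, per-class probabilities as an option
   — are concatenated (width 3C = 6) and a fully connected meta head
   (a single linear layer by default; `meta_hidden > 0` inserts a
   hidden ReLU layer) is trained with the same loss and optimiser.
   Joint fine-tuning of bases and meta head is available behind
   `freeze_bases=False` but is not the default.
5. **Evaluation.** Stratified 10-fold cross-validation: per-fold class
   counts are within one subject of the global proportions. Class
   imbalance is corrected per training fold by upsampling (duplicating
   randomly chosen minority subjects, never dropping anyone) or
   downsampling (random majority subset, never duplicating anyone).
   ACC, SEN and SPE are the confusion-matrix ratios
   (TP + TN)/total, TP/(TP + FN), TN/(TN + FP); a zero denominator
   yields an explicit null, never a silent 0. AUC is the trapezoidal
   area under the ROC of the positive-class softmax probability,
   computed per fold and averaged with unweighted means (as are the
   other metrics). Patients are the positive class by default;
   `positive_class` is configurable.

## Design choices that were genuinely open

* **k = 10 neighbours.** The sparsification level is not a property of
  the data but a modelling choice; k = 10 keeps ~17 % of edges at
  R = 60 and ~6 % at R = 160, dense enough for connected graphs and
  sparse enough that attention neighbourhoods stay local. It is a
  mandatory config surface (`GraphConfig.k`); doubling or halving k
  mainly changes how much the weighted degree normalisation smooths
  the GCN propagation.
* **Sign handling.** Negative correlations are ranked by magnitude and
  enter the adjacency as |z|; the signed values remain in the node
  features, so no information is discarded, and the GCN degree
  normalisation stays real.
* **Meta input = logits.** "Output features" of a softmax-terminated
  base are taken to be its pre-softmax logits, since the ensemble
  itself applies the final softmax; probabilities are available via
  `combine="concat_probs"`.
* **Resampling direction.** Upsampling duplicates the minority class
  and downsampling subsets the majority (the balanced-count
  definition); after either, class counts are equal.
* **Resampling scope.** The default `train_folds_only` balances each
  training fold after the split, so no test subject can appear in
  training. The alternative `before_split` balances the whole cohort
  first and then splits; duplicated subjects can then straddle the
  train/test boundary, and the pipeline counts and reports this
  leakage rather than hiding it. The contrast between the two scopes
  is itself a result the package exposes: before-split upsampling
  inflates apparent accuracy through duplicate leakage.
* **Epochs 150, batch size 32** as training defaults; both are config
  surfaces. Evaluation studies in this repository use 50 epochs, which
  is past loss convergence on the synthetic conditions below.
* **GAT output layer width.** Head-averaging on the last attention
  layer uses the same per-head width (8) as the hidden layers, giving
  parity with the per-head feature budget rather than with the
  concatenated width.

## Numerical core

No GPU deep-learning framework is used: the models run on a compact
reverse-mode autodiff engine (`fcgnn._tensor`) over numpy, with
message passing expressed as sparse CSR matrix products (constant
operators for normalised-adjacency propagation, neighbour means and
mean pooling; per-head data-swapped CSR products for attention
aggregation). The engine is validated against central finite
differences, and each layer against an independent oracle (dense
matrix algebra for GCN, a per-node loop for GraphSAGE, softmax
normalisation identities for GAT). Training numerics are float32; the
public layer functions and all metric arithmetic run in float64.
Attention softmax is stabilised by subtracting the per-neighbourhood
maximum (exact, by shift invariance). Adam follows the standard
formulation with weight decay added to the gradient before the moment
updates. All randomness — initialisation, epoch shuffling, dropout
masks, fold assignment, resampling — flows from explicit integer
seeds, so a run is bitwise reproducible on a given platform; per-fold
and per-architecture seeds are derived from the user seeds with a
fixed integer hash.

Degenerate inputs: zero-variance regions raise an error naming the
region; ties in class probabilities resolve to class 0; metrics with
empty denominators are reported as nulls and excluded from fold means.

## Synthetic cohorts

The real multi-site patient/control cohort this pipeline targets is
access-restricted, so the package ships a generator whose defaults
define the study conditions. Each subject's matrix is
`base_connectivity` (0.3, a typical resting-state mean z) plus
independent Gaussian edge noise; group-1 subjects additionally carry
`effect_size` on a connected random subset of 50 edges (connected, so
the signal is not a single-node artefact); optional per-site offsets
model scanner shifts. Presets:

| preset     | groups    | effect (z) | noise sd |
|------------|-----------|------------|----------|
| separable  | 100/100   | 1.5        | 0.2      |
| moderate   | 100/100   | 0.4        | 0.3      |
| null       | 100/100   | 0.0        | 0.3      |
| imbalanced | 110/55    | 0.8        | 0.3      |

The imbalanced preset mirrors the roughly 2:1 first-episode/recurrent
subgroup imbalance of the motivating cohort.

What the generator does **not** emulate: correlated edge noise,
positive-definiteness of the underlying correlation structure,
heavy-tailed site effects, or realistic BOLD dynamics. Passing the
recovery tests therefore demonstrates that the pipeline detects
localised mean-connectivity differences of a stated magnitude under
independent noise — not that it attains any particular accuracy on
real scans.

## Problem sizes used in the shipped studies

The evaluation studies run at R = 60 regions, 100 subjects per group,
10 folds and 50 epochs (the imbalanced leakage contrast at R = 24,
2 epochs, since the leakage count is a property of the fold/resampling
protocol, not of training quality; the byte-reproducibility check at
30/30 subjects, R = 30, 5 epochs, since determinism does not depend on
problem size). These sizes are the package's own defaults for its
synthetic studies; `n_regions` scales to 160 unchanged.

## Known limitations

* Full-batch message passing per mini-batch of graphs; no neighbour
  sampling, so very large R would need the batch size reduced.
* No site harmonisation or nested hyperparameter tuning; the CV
  protocol evaluates a fixed configuration.
* The ensemble is not guaranteed to beat its best base — with a single
  linear meta layer on 6 features it can at best reweight the bases;
  the tests encode this with a tolerance rather than a strict
  improvement claim.
* AUC is computed per fold and averaged; pooling predictions across
  folds before the ROC would give slightly different values.
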