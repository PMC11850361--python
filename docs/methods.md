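# Methods

`mdlink` predicts unobserved microbe–disease associations from a curated
binary association table by learning node embeddings on a heterogeneous
similarity/association network and reconstructing the full association
probability matrix. This note documents the model, the numerical
choices behind it, what the synthetic benchmark does and does not show,
and the package's known limitations.

## Problem setting

The input is a deduplicated list of known (microbe, disease)
associations, equivalently a binary matrix **A** ∈ {0,1}^(Nm×Nd) whose
rows are microbes and columns diseases. Known entries are a tiny,
positive-only sample of the true interaction structure; the task is to
rank the unknown pairs so that true-but-unrecorded associations surface
at the top. Evaluation is by repeated k-fold cross-validation over the
known positives: each fold's positives are hidden from training and
then ranked against all unknown pairs (AUC, plus thresholded accuracy
and specificity).

## Similarity views

Each side of the bipartite network gets three similarity views,
averaged elementwise into an integrated matrix (MS for microbes, DS for
diseases):

1. **Gaussian interaction profile (GIP) kernel.** For profiles p_i
   (rows of A for microbes, columns for diseases),
   `S(i,j) = exp(−λ‖p_i − p_j‖²)` with bandwidth
   `λ = 1 / mean_i ‖p_i‖²`. The kernel is 1 on the diagonal and decays
   with profile disagreement.
2. **Cosine similarity** of the same profiles. An all-zero profile has
   no direction; such entities score 0 against everything and 1 against
   themselves.
3. **A functional view.**
   - *Diseases*: gene-set similarity. Gene–gene interaction scores
     (log-likelihood scores, LLS) are min–max normalized to a gene
     functional similarity FSS ∈ [0,1] (1 on self-pairs, 0 for pairs
     absent from the net). Disease pairs are compared by the
     best-match-average of their gene sets:
     `DFS(di,dj) = (Σ_{g∈Gi} max FSS(g,Gj) + Σ_{g∈Gj} max FSS(g,Gi)) / (|Gi|+|Gj|)`.
   - *Microbes*: semantic similarity of their associated disease sets
     over a disease DAG. A term contributes `0.5^ℓ` to a descendant ℓ
     edges below it (best path; `SC`), terms sum to the semantic value
     `SV`, and two diseases are compared by their shared-ancestor
     contributions normalized by `SV(di)+SV(dj)` (`DSS`). Disease sets
     are then compared best-match-average style (`MFS`).

When the functional inputs (gene net, DAG) are not supplied, the
integration falls back to the mean of the two profile views and logs
the fallback; everything downstream is unchanged. Diseases missing
from the DAG, gene-less diseases, and association-less microbes score 0
off-diagonal in the affected view — neutral and bounded.

## Heterogeneous network and features

The network over all Nm+Nd nodes (microbes first) is

    Y = [[w·MS, A], [Aᵀ, w·DS]]

with similarity weight w = 6 by default, putting the similarity blocks
on a comparable footing with the binary association block. Initial
node features are the rows of Y itself (`feature_scheme="hetnet"`),
which injects every similarity and association value with zero extra
parameters; identity features are available (`"onehot"`). Both
encoders consume the symmetric normalization
`D̂^(−1/2)(Y+I)D̂^(−1/2)`; the attention channel's neighbor sets are
the nonzero entries of that matrix.

Block orientation (microbes first vs diseases first) only relabels
node indices; the node ordering is recorded in run manifests because
the recurrent stage is order-sensitive.

## Model

Two parallel encoder channels, L=2 layers each, embedding width k:

- **GCN channel**: `H^{l+1} = ReLU(D̂^{-1/2}ÂD̂^{-1/2} H^l W^l)` —
  smooths features over the weighted neighborhood structure.
- **GAT channel**: per-edge attention logits
  `LeakyReLU(a^T[Wh_i ‖ Wh_j])` (slope 0.2), softmax-normalized over
  each node's neighborhood, then `ReLU(Σ_j α_ij W h_j)`. Single head;
  attention rows sum to one by construction.

The channel outputs are concatenated (width 2k) and passed through a
bidirectional LSTM along the node axis — each node is one time step,
in the fixed input ordering — with total output width `lstm_hidden`
(split across directions). A fully connected layer projects each node
to a k-vector z, and pair (i,j) is scored
`ŷ_ij = logistic(z_mi · z_dj + b0)` with a single learnable scalar
bias b0. Ablation switches remove one channel (the surviving channel
is duplicated so downstream shapes are unchanged) or bypass the
recurrent stage (the decoder then reads the fused matrix directly).

The loss is mean binary cross-entropy between ŷ and the (masked)
association matrix — by default every unknown pair counts as a
negative; a per-epoch balanced negative sample is available — plus an
L2 penalty `λ Σ_k ‖W_k‖²` over the weight matrices (biases and
attention vectors excluded), λ = 5·10⁻⁴ by default.

## Training: numerical choices

All layers run on a small in-package reverse-mode autodiff engine over
dense NumPy arrays (`mdlink/_autodiff.py`); gradients are validated
against finite differences in the test suite. The graphs at target
scale (≲1,300 nodes) are dense-friendly, so no sparse machinery is
used.

- **Optimizer**: Adam, initial learning rate 0.01, with cosine decay
  of the learning rate to zero over the configured epochs. The decay
  matters: with a constant rate, isolated loss spikes late in training
  can throw the recurrent stage into a poor basin just before the
  epoch budget ends.
- **Gradient clipping**: global norm clipped at 5 (`grad_clip`;
  0 disables). Typical gradient norms are ~0.1; the clip only
  intervenes on rare spikes.
- **Initialization** (seeded, uniform Glorot-style): encoder weights
  by fan; LSTM input/recurrent weights per-gate (fan_out = hidden, not
  4·hidden). LSTM gate biases start near-feedforward — input and
  output gates at +2 (mostly open), forget gate at −2 (mostly shut) —
  so node features reach the decoder from epoch 0 and recurrent
  dependencies are learned in gradually. Without this the recurrent
  stage spends most of a short epoch budget in a plateau.
- **Dropout** (training only, inverted scaling): elementwise masks on
  the normalized adjacency (rate `dropout_adj`, no degree
  renormalization afterwards) and on features after every encoder
  layer (rate `dropout_feat`); both default 0.5. Inference is
  deterministic — dropout off.
- **Stability**: predictions are clamped to [1e−12, 1−1e−12] inside
  the loss; a NaN loss aborts with a diagnostic rather than training
  through it.
- Cross-entropy uses all matrix entries; `balanced` mode draws
  |positives| negatives per epoch from the seeded generator.

Defaults follow the reference protocol where one exists: k = 128,
L = 2, `lstm_hidden` = 128 (bidirectional), 4,000 epochs, lr 0.01,
dropout 0.5, similarity weight 6, 5-fold CV repeated 5 times. The
benchmark runs in the tests and the acceptance script use k = 32 and
500 epochs at the fixture scale below, with single repeats, so the
whole suite completes on one CPU in minutes.

## Cross-validation hygiene

Fold splits partition the known positives with a seeded shuffle. For
every fold, the test positives are zeroed in the training adjacency
**and every similarity matrix is recomputed from the masked
adjacency** — GIP and cosine profiles, and the microbe functional view
(whose disease sets come from the adjacency), would otherwise leak
held-out edges into training. Externally supplied gene nets and DAGs
are not functions of A and carry no leakage. Held-out positives are
scored against all pairs unknown in the *full* data, the common
convention in association benchmarking; sampled-negative evaluation
would shift absolute AUC values.

## The synthetic benchmark

`synthetic_data` generates the entire input family without downloads:

- **Associations**: microbes and diseases assigned round-robin to
  `n_blocks` latent blocks; a pair associates with probability `p_in`
  inside its block, `p_out` outside. The benchmark fixture is 60×20,
  4 blocks, p_in = 0.5, p_out = 0.02 (~150 positives, ~12% density) —
  informative profile kernels without trivial separability.
- **Gene net / disease–gene map**: uniform LLS in [0,5]; each disease
  draws 1–5 genes mostly from a block-private pool, so same-block
  diseases have higher functional similarity.
- **Disease DAG**: a rooted tree with one subtree per block (depth
  bounded by `dag_depth`), so same-block diseases are semantically
  closer.

All generators are pure functions of (spec, seed). Because every
similarity view correlates with the planted blocks, the benchmark
exercises each path of the pipeline and has a known recoverable
signal: the full model's 5-fold CV mean AUC lands around 0.88–0.90 at
the benchmark settings, a label-shuffled control sits near 0.5, and a
similarity-only one-hop baseline (MS·A + A·DS) sits around 0.80 —
i.e. the learned model adds real margin over its own inputs.

What passing these tests does **not** show: real association tables
have heavy-tailed degree distributions, name-harmonization noise,
block structure that is at best approximate, and curation bias in
which pairs get studied. Synthetic recovery demonstrates correctness
of the machinery, not field performance on curated databases.

## Known limitations

- Transductive only: nodes unseen at training time cannot be scored.
- The recurrent stage is order-sensitive by design (the node sequence
  is the first-appearance input order, recorded in manifests);
  encoder layers are permutation-equivariant but the full model is
  not.
- Single-head attention; no edge features; dense O(n²) memory.
- Determinism is per-platform: identical seeds reproduce trajectories
  bitwise on one machine, not necessarily across BLAS builds.
- With `folds` close to the positive count, masked adjacencies can
  contain all-zero rows/columns; the similarity conventions above keep
  the pipeline defined, but such folds carry little signal.
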