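# Methods

## Problem and model

Experimentally confirmed miRNA–disease associations (MDAs) are sparse;
predicting unobserved ones from complementary evidence — sequence, target
genes, disease ontology, disease genes — is a bipartite link-prediction
problem on a heterogeneous network. `mvifmda` implements a multi-view
information-fusion predictor:

1. **Similarity views.** Four node-similarity matrices are computed from raw
   inputs:
   - *disease semantic* `SD1`: in a MeSH-style DAG, every ancestor `t` of a
     disease `d` contributes `D_d(t)`, with `D_d(d) = 1` and
     `D_d(t) = max{ Δ · D_d(t') : t' child of t }` otherwise; similarity is
     the shared-ancestor contribution mass (counted from both diseases) over
     the two total masses. `Δ = 0.5` by default.
   - *disease/miRNA functional* `SD2`/`SM2`: best-match-average between the
     two entities' gene sets over a weighted gene functional network; the
     gene–gene score is 1 for identical genes and the min–max-normalized
     log-likelihood score (LLSN ∈ [0,1]) of the edge otherwise (0 when
     unlinked). An empty gene set carries no evidence and yields similarity 0
     (warned).
   - *miRNA sequence* `SM1`: Needleman–Wunsch global alignment scores
     (match 1, mismatch −1, linear gap −1 by default; the normalization
     removes the scale), min–max normalized over the off-diagonal pairs and
     the diagonal then fixed at 1, so a single long sequence cannot flatten
     the matrix.
2. **Heterogeneous views.** With associations `A` (binary, `Nm × Nd`), each
   pairing of one miRNA similarity with one disease similarity gives a view
   `M = [[SM, A], [Aᵀ, SD]]`; four views in the fixed order (SM1,SD1),
   (SM1,SD2), (SM2,SD1), (SM2,SD2). Node order is miRNAs first, then
   diseases, asserted in one place and relied on everywhere.
3. **Topology branch.** Each view gets its own L-layer GCN,
   `X^(l+1) = σ(D^{-1/2} M D^{-1/2} X^(l) W^(l))` with `X^(0) = M`, ReLU at
   every layer, separate weights per view and layer. All `n·L` layer outputs
   are stacked; an attention layer scores each representation
   (`s_i = qᵀ tanh(W_a x + b_a)` applied per node row, averaged over nodes)
   and the softmax weights form the fused topology embedding.
4. **Attribute branch.** The stacks of raw similarity matrices are encoded by
   a one-layer CNN whose filters span a full column (height = entity count,
   width 1, no padding); one filter per output channel is shared across the
   stacked views (matching the printed filter shape), which is equivalent to
   convolving the view-sum, plus a per-position bias per channel.
5. **Decoder and loss.** Topology and attribute embeddings are concatenated
   per entity and every pair scored by `A' = sigmoid(Z_m W_b Z_dᵀ)`. The loss
   is the *summed* cross-entropy over all `Nm × Nd` pairs — known pairs
   positive, every other pair negative, no negative subsampling and no
   normalizer — minimized by Adam.

## Parameters

| name | default | meaning |
|---|---|---|
| `n_layers` (L) | 2 | GCN depth per view |
| `f_topology` | 256 | width of every GCN layer / fused embedding |
| `f_channel` | 256 | CNN output channels |
| `lr` | 1e-3 | Adam learning rate |
| `epochs` | 200 | full-batch training epochs |
| `delta` (Δ) | 0.5 | semantic-contribution decay per DAG generation |
| NW scheme | (1, −1, −1) | match / mismatch / linear gap |
| `use_topology` / `use_attribute` | on | ablation switches (off = the noTR / noAR variants) |

200 epochs puts training in the slow tail of the loss curve on the default
synthetic preset; training substantially longer degrades held-out ranking as
the attribute branch's free per-position bias (a learnable per-node vector)
starts memorizing the training matrix. Early stopping on a training-loss
plateau is available (`early_stop_patience`) but off by default: the loss
rises transiently during the first ~30 epochs before descending, which a
plateau detector misreads.

## Numerical choices

- **Autodiff.** The model is trained with a small reverse-mode
  tape (`mvifmda.autodiff`) over numpy in float32; every primitive and the
  assembled loss are checked against central finite differences in the test
  suite. Same seed ⇒ bit-identical runs on one BLAS configuration.
- **Decoder initialization.** The bilinear form sums `(f_topology +
  f_channel)²` terms, so fan-based initialization of `W_b` saturates the
  sigmoid at epoch 0 (clamped scores, dead gradients); `W_b` starts at 0.05×
  its fan-based scale so optimization begins near logit 0.
- **Degenerate inputs.** Degrees are floored at 1e-12 in the GCN
  normalization; sigmoid outputs are clamped to [1e-10, 1−1e-10] before the
  log (warned); an all-equal alignment-score matrix is a reported error
  rather than a silent constant; ranking ties break by identifier.
- **Attention reduction.** The attention projection maps a whole node ×
  feature matrix; reducing it to one scalar per representation is done by
  applying the projection per node row and averaging over nodes — a
  permutation-invariant choice made here, with per-representation softmax as
  required. Sum-over-nodes would only rescale the logits.
- **Evaluation.** Per CV fold the candidate set is every pair that is not a
  *training* positive; held-out positives are the positives. AUC is the
  rank-statistic ROC area, AUPR the precision–recall step integral
  (scikit-learn), so AUPR lives on a small scale at realistic sparsity.
  precision@k% / recall@k% take the top k percent of the fold's full
  descending ranking. The confusion threshold is 0.5.

## Synthetic data

Real association catalogues, MeSH, gene annotation databases and miRNA
sequence archives cannot be bundled, so the generator plants one latent
mechanism — `C` hidden clusters over both entity types — into all five
inputs: associations are Bernoulli(`p_in` = 0.25) within matched clusters and
Bernoulli(`p_out` = 0.01) otherwise; same-cluster diseases hang under shared
deep anchor chains of the DAG; gene sets draw ~80% from per-cluster gene
modules wired densely (edge prob 0.3, LLS ∈ [3,5]) against a sparse weak
background (0.01, LLS ∈ [0.5,1.5]); sequences are per-site substitutions
(rate 0.15, no indels, keeping alignment scores monotone in cluster
distance) of per-cluster prototypes of 20–24 nt. The default study size is
200 miRNAs × 80 diseases × 5 clusters (~940 positives at seed 1), small
enough that a full 5-fold cross-validation runs in a few minutes on one CPU.
`null_copy` re-draws the associations uniformly at the exact same density
without touching the similarity inputs, which removes every recoverable
signal and pins chance-level AUC.

What the generator does **not** emulate: the heavy-tailed degree
distributions of curated catalogues, correlated annotation noise across
sources, incomplete DAG coverage, and the ~100× larger scale of real
studies. Passing the recovery tests therefore shows the pipeline can exploit
coherent multi-view signal, not that it attains any particular accuracy on
real data.

## Observed behavior and limitations

- On the default planted preset, 5-CV mean AUC is ≈ 0.85 for the full model
  and ≈ 0.52 on the null copy — the headline planted/unplanted gap.
- The ablation variants are *not* cleanly dominated at this scale: the
  topology-only variant (noAR) reaches ≈ 0.855, slightly above the full
  model, and the attribute-only variant (noTR) is within ~0.001 of it. The
  synthetic similarity views are clean block-structured cluster signals, so
  a single branch already captures essentially everything recoverable, and
  the second branch mostly adds capacity (and mild overfitting) rather than
  information. The corresponding acceptance test asserts the strict
  full-dominates-both ordering and is expected to fail at desk scale; the
  fusion advantage this architecture is designed for presupposes
  complementary, noisy real-world views.
- Training is full-graph and dense; memory scales as O((Nm+Nd)²) and the
  implementation targets a few thousand entities at most.
- The evaluation treats all unobserved pairs as negatives; metrics are
  therefore lower bounds in the presence of undiscovered true associations.
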