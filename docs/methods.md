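# Methods

This note documents the models implemented in `protomap`, the choices made
where the design was genuinely open, the synthetic data the tests run on,
and what those tests do and do not establish.

## Data model and normalization

All stages exchange `ExpressionDataset` objects: a nonnegative
cells × features matrix with ordered feature/cell identifiers, a per-cell
dataset (batch) index, optional cell-type labels, and optional 2-D spot
coordinates. Normalization is the standard single-cell chain, in this
exact order: per-cell library-size scaling to `target_sum` (default 10⁴,
the common convention), `log(1+x)`, then min-max scaling **per feature**
across cells. Per-feature (rather than global) min-max was chosen because
every downstream component treats features as tokens with their own linear
projection of the expression value; a per-feature [0, 1] range makes that
projection's input scale uniform across tokens. Constant columns map to
all zeros (avoiding 0/0), and normalization is guarded by a flag so it
cannot be applied twice.

Split regimes: `random` (uniform), `few_shot` (|train| =
round-half-up(fraction·n), floored at one cell), `ood` (entire cell types
held out of training), and `zero_shot` (everything is test; training
happens on another assay).

## PPI embeddings

Feature identity is injected through fixed per-feature vectors learned
from a weighted protein–protein interaction edge list by link prediction:
embeddings are trained so that the sigmoid of the endpoint dot product
discriminates observed edges (weighted by confidence) from sampled
non-edges, and quality is reported as AUC on a held-out edge set. This is
a plain dot-product embedder rather than a binding to any external
embedding tool: the downstream contract needs nothing more than fixed
vectors keyed by feature ID, and a self-contained implementation is
testable end to end. Features absent from the network receive zero
vectors, so their tokens gracefully reduce to the expression projection.
The embedding width defaults to the encoder model dimension so the
additive token construction is dimension-consistent; a linear adapter maps
imported tables of any other width.

## Encoders and masked pretraining

Token *i* of a cell is `g_i = expr_projection(x_i) + ppi_adapter(x_i^ppi)`
— no positional encodings, so encoding is permutation-equivariant in the
tokens and identity is carried entirely by the PPI/ID embeddings. A
learnable pooling (cls) token is prepended; padding tokens are excluded
from attention and pooling. Two poolings are provided: the mean over real
feature tokens (used during pretraining) and the cls row (used during
contrastive fine-tuning); both views appear in the literature and the
enum keeps them interchangeable.

Pretraining masks a random 30 % of each cell's feature tokens (resampled
every epoch, never the cls or padding positions), replaces them with a
learnable mask token, and minimizes mean squared error **on the masked
positions only**. Predicting a whole masked vector from one pooled cell
vector is ill-posed per position, so the reconstruction head takes the
concatenation `[z ; id-embedding of the masked feature]` and emits one
scalar per masked position — the pooled state supplies the cell context,
the ID embedding identifies which feature is being asked for.

Batch structure is handled by dataset tokens: `z = c + α·b_d` with one
learnable vector per training dataset and a single learnable scale α.
Unseen dataset indices at inference use the zero batch vector and emit a
warning.

Attention is exact softmax attention by default; a positive-random-feature
(FAVOR-style) linear-attention variant is provided for long token panels
and agrees with exact attention to within 1e-2 cosine distance on pooled
embeddings at desk scale (a tested contract). When feature count exceeds
`max_tokens`, the highest-variance features are kept, ties broken by
feature ID.

**Optimizer defaults.** Adam with gradient clipping at global norm 1,
learning rate 3e-3, pretraining minibatch 32, one transformer layer with
two heads at model dimension 32. These are desk-scale choices: at the
problem sizes the package targets (hundreds to thousands of cells, tens
to low hundreds of features) the smaller batch and higher rate give the
masked objective enough optimization steps to clearly beat a per-feature
mean imputer within a few dozen epochs, which a 1e-3/large-batch setting
does not. All parameters are float64-initialized from explicit generators;
the training engine stores tensors in float32 (a module-level switch
allows float64, which the gradient-correctness tests use).

## Contrastive alignment

Given index-paired RNA/protein datasets (identical cell IDs in identical
order — validated, since silent misalignment is the classic failure
mode), both encoders are fine-tuned with the symmetric InfoNCE loss: the
cosine-similarity matrix of the minibatch is scaled by a temperature τ
(default 0.07, learnable by default, the CLIP convention) and the row-
and column-softmax cross-entropies on the diagonal are averaged.
Embeddings pass through a small linear projection head (width = model
dimension) before the cosine; the head is toggleable so the ablation
without it remains expressible. Negatives come from the minibatch only.

## Translation

RNA → protein prediction is framed as translation: an MLP expands the
aligned RNA cell embedding into `m = 8` slot vectors (more than one slot
makes cross-attention non-trivial; kept small for desk scale). Each
protein's query vector is the protein encoder's pooled output for a
single identity token — its learned ID embedding plus adapted PPI vector,
no expression value — with batch-token integration. Scaled dot-product
attention over the slots yields a context vector, and a linear head with
a learnable bias (the bias absorbs the normalized-intensity offset;
toggleable) produces the prediction. Training minimizes MSE against
normalized protein intensities; encoders are frozen by default so
translation capacity is separated from alignment quality. Raw head
outputs are kept available, and inference clips to [0, 1] to honor the
normalized target range. Any protein in the encoder vocabulary can be
queried, so predicted panels may exceed every measured panel.

## Spatial mapping

Cells are assigned to spots by a softmax over spots of the embedding
cosine similarities at matching temperature τ_m (default 0.1 — sharper
than the contrastive temperature, since assignment should commit more
than alignment training does). Rows of the assignment matrix are
stochastic by construction (max-subtraction stabilized). The literal
projection `x̂ = Wᵀ·pred` sums cell predictions with weights normalized
over spots, so a spot's incoming weights need not sum to one; by default
the projection renormalizes per spot, making it a weighted mean that
stays on the normalized intensity scale (the literal weighted sum remains
available via flag). An optional top-K row truncation (K = 50) is provided
for large instances, off by default. Cell-type label transfer uses the
same weights: each spot receives the weighted label histogram of all
cells, renormalized.

## Evaluation metrics

* Per-cell cosine, Pearson, and Spearman (average ranks on ties) between
  true and predicted protein profiles; cells with zero variance in either
  vector are excluded from the correlation means and counted.
* FOSCTTM with Euclidean distance by default (cosine by flag) and average
  ranks on ties, so duplicated distances cannot game the score; 0 is
  perfect, 0.5 is chance.
* Match score: fraction of cells whose cross-modal nearest neighbor is
  the true partner; ties break toward the smallest index and are warned
  about.
* Top-k % cell-type matching: fraction of queries whose label appears
  among the top ⌈k %⌉ most cosine-similar references; top-1 label
  accuracy stands in for plain retrieval accuracy.
* Moran's I on a symmetric, row-standardized k-nearest-neighbor weight
  graph (k = 8 default; the weight scheme is a free choice and is recorded
  in the report). Null expectation under permutation is −1/(n−1).
* Spatial MMD: squared maximum mean discrepancy between two weighted 2-D
  point sets under a Gaussian kernel of bandwidth `blur` (the spatial
  scale compared), estimated as a biased V-statistic — stable for
  weighted spot sets — and clamped at zero. Spatial distributions are
  expression-weighted point sets (weight = intensity or label indicator).

## Synthetic data: what it emulates and what it does not

The generator draws, per cell, a type from a uniform multinomial and a
latent factor vector around the type's mean (type means scaled Gaussian,
spread 0.4); both modalities observe
`softplus(latents · loadingsᵀ + batch offset + Gaussian noise)` with
modality-specific loading matrices. The softplus link keeps expression
nonnegative while remaining smooth; batch effects are additive
per-feature offsets drawn once per batch and applied before the link —
exactly the dataset-level variation the batch token is meant to absorb.
Spatial fixtures place type centers uniformly in the unit square and
scatter cells around them (SD = `spatial_cluster_scale`), then expose only
the first `measured_panel_size` proteins with fresh measurement noise.

Defaults — 2,000 cells, 100 genes, 30 proteins, 8 shared factors, 4 cell
types, 2 batches, noise SD 0.1, batch-effect SD 0.3, cluster scale 0.05,
20-marker measured panel — are the package's study conditions: large
enough that alignment must recover within-type structure (type identity
alone would leave FOSCTTM near 0.125), small enough to train on one CPU.
The interaction-network fixture is a stochastic block model whose node IDs
reuse the expression feature names.

Deliberately not modeled: count-level noise (negative-binomial dropout),
doublets, segmentation artifacts, antibody cross-reactivity. Passing
tests therefore demonstrate that the architecture and objectives recover
a shared low-rank latent structure under Gaussian noise and additive
batch effects — not that the pipeline is robust to the full noise
anatomy of real CITE-seq or CODEX data.

## Numerical and engineering notes

* All randomness flows from explicit integer seeds; generators are pure
  functions of (config, seed), and trained models are reproducible to
  floating-point reduction order at a fixed thread count.
* The contrastive loss and all metrics are computed in float64; training
  tensors are float32.
* Softmaxes are max-subtraction stabilized everywhere; the linear-
  attention denominator is floored at 1e-12; row normalizations guard
  zero sums.
* The end-to-end pipeline writes a manifest with resolved configs,
  per-stage metrics, and content checksums of all artifacts, so reruns
  can detect drift.
* Test problem sizes: the recovery experiments use the default 2,000-cell
  fixture at three seeds with 5 pretraining epochs (batch 128) and 40
  contrastive epochs; the pretraining-signal check uses a 500-cell rank-4
  fixture for 30 epochs. These sizes were chosen as the smallest at which
  the measured effects are stable across seeds.

## Known limitations

* Single-token protein queries: the protein encoder could alternatively
  be queried with a full reference panel per dataset; the single-token
  variant was implemented because it needs no reference expression at
  inference time.
* The spatial projection is purely embedding-driven; no histology,
  morphology, or spatial regularization informs the assignment.
* Linear attention is an approximation with a tested tolerance at desk
  scale; very long panels with highly peaked attention may exceed it.
* The pipeline trains each modality encoder on one dataset list with a
  shared vocabulary; cross-dataset vocabularies are harmonized by
  intersection/union utilities, not by any gene-symbol mapping.
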