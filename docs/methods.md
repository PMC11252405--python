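# Methods

`oncomod` predicts cancer genes from a protein–protein interaction (PPI)
graph carrying multi-omics node features, and then dissects each prediction
into a compact "gene module" — the small connected neighborhood of
interactions and the input features most responsible for that gene's score.
This note describes the model, the preprocessing conventions, the
synthetic-data generator the test suite runs on, and the numerical choices
made where the design was genuinely open.

## Input features

Each gene is a node; its feature vector concatenates, in fixed order:

| block | cell-line mode | patient mode |
|---|---|---|
| ATAC promoter density | 1 | 1 |
| CTCF promoter density | 3 replicates | 1 |
| H3K4me3 promoter density | 2 replicates | — |
| H3K27ac promoter density | 2 replicates | 1 |
| CNV frequency | 1 | — |
| SNV frequency | 1 | — |
| Hi-C (SVD) | 5 | 5 |
| **total** | **15** | **8** |

*Coordinates* are 0-based half-open (BED convention); the TSS is the
strand-aware gene edge. *Promoter density* is the length-weighted mean
signal over TSS ± 1 kb, with uncovered bases contributing zero; the divisor
is the full window width, so the value is invariant to splitting a track
interval into abutting pieces. The field's usage of "density" is ambiguous
(sum vs. mean); the mean was chosen because it is resolution-independent.

*CNV frequency* of gene *i* is `Σ_s v_si / |S|` over the sample set *S*.
*SNV frequency* is `1000 · Σ_s v_si / (|S| · len_i)`: non-silent mutation
counts (records whose classification is in a configurable silent set,
default `{"Silent"}`, are dropped first), normalized by gene length,
averaged over samples, and magnified ×1000 to a feature-friendly scale.
Because the expression is linear, whether the magnification is applied
before or after averaging is immaterial.

*Hi-C features.* The binned contact matrix is balanced by plain iterative
correction (repeatedly dividing rows/columns by their marginal relative to
the mean, all-zero rows excluded) until the coefficient of variation of the
nonzero marginals falls below 1e-5 (max 200 iterations). Eigenvector
decomposition is not performed — nothing downstream consumes compartment
calls, only the balanced matrix. Structural-variant correction of the raw
contacts is an external pre-step and out of scope. The gene contact matrix
`C` sums balanced counts over all bin pairs overlapping the two gene
bodies; it is then condensed genome-wide (inter-chromosomal contacts are
part of `C`) by truncated SVD to k = 5 per-gene coordinates `(U_k Σ_k)[i]`.
Signs are fixed by forcing the largest-magnitude entry of each left
singular vector positive, making the embedding deterministic; large inputs
go through a sparse truncated solver with a fixed start vector, which
returns the same top-k factors as a dense SVD.

The alternative "contacts as edges" graph builders (unweighted,
`log10(1 + c)`, `c^{1/10}`) are provided for ablation-style experiments;
the +1 offset keeps the log finite for the sub-unit values balancing
produces.

All feature columns are z-scored over all genes (labeled and unknown);
zero-variance columns map to zero.

## Graph and labels

PPI edges with confidence below 0.5 are dropped (the boundary value 0.5 is
kept), edges are symmetrized and de-duplicated, self-loops removed, and
degree-0 genes pruned. Labels are tri-state: 1 (known cancer gene),
0 (confident non-cancer gene), −1 (unknown). Unknown genes participate in
message passing but never in the loss — the semi-supervised setting.

25 % of the labeled genes (stratified) form the held-out test set; the rest
are dealt per class, after seeded shuffling, round-robin into ten folds, so
per-fold label counts stay within one gene of the global ratio even for
very small classes.

## Model

Two multi-head graph-transformer convolutions with scaled-dot-product
attention over neighbors:

    x'_i = W1 x_i + Σ_{j∈N(i)} α_ij W2 x_j,
    α_ij = softmax_j( (W3 x_i)ᵀ (W4 x_j) / √d )

N(i) excludes the node itself (the self-contribution is the W1 term). The
softmax over neighbors is part of the attention operator even though the
raw score formula alone does not show it. Four heads of width d = 16
(concatenated to 64) were chosen so that max-pooling with stride 2 yields
the 32-dimensional pooled representation. Each convolution is followed by
layer norm (per-node mean/variance, population variance, learnable affine).
The second convolution runs on the residual concatenation `[h_i, x_i]` of
the first layer's output with the raw input — this keeps the raw features
available and counteracts over-smoothing. After pooling: linear 32→32,
ReLU, dropout, linear 32→1, sigmoid. Dropout is 0.1 on attention weights
and 0.4 elsewhere, training only.

Loss is binary cross-entropy on labeled training nodes, computed from
logits in the numerically stable form. Optimization uses Adam with a
learning rate that rises linearly from 0 to 0.005 over the first 20 % of
optimizer steps and stays at the peak; "steps" are full-batch epochs.
Because the network has exactly two message-passing layers and the exact
1st+2nd-order neighborhood of a node determines its output, full-graph
training computes the same function as per-node two-hop subgraph batching,
so training is implemented full-batch. Early stopping monitors validation
AUPRC (the metric was not prescribed; AUPRC is the natural choice under
class imbalance) with patience 100 epochs, restoring the best-epoch
weights. Before training, a seeded half of the training-pool negatives
(`floor(0.5·n_neg)`) is removed once per run — the same removal set for
every fold — and validation/test genes are never touched.

Ten models (one per fold) are trained; reported scores are the arithmetic
mean of their sigmoid outputs. For transfer, a model pretrained on one
dataset is fine-tuned on another with the same feature width; zero
fine-tuning epochs returns the pretrained predictions unchanged.

The whole network runs on a small reverse-mode autodiff engine over numpy
(`oncomod._autodiff`), whose primitives are finite-difference tested; no
deep-learning framework is required.

## Explainer

For a query gene, the computation subgraph is its exact two-hop
neighborhood. A learnable mask logit is attached to every undirected edge
(applied, after a sigmoid squash, to both message directions — symmetry
holds by construction) and to every input feature column. Masks are
initialized near 1 (logits ~ N(1, 0.1), seeded) so the initial masked
prediction equals the original; setting all masks to exactly 1 reproduces
the model's prediction bit-for-bit.

The mutual-information objective (find the small subgraph/feature subset
that retains the information the model used) is not directly computable;
the standard surrogate is minimized instead: keep the masked prediction at
the model's original decision while penalizing mask mass and mask entropy.
When the model exposes pre-sigmoid logits the prediction term is the
(signed) logit rather than the cross-entropy — a well-trained model
saturates its probabilities, and the cross-entropy gradient with respect to
the masks then vanishes, leaving rankings to noise; the logit keeps a
usable gradient. Defaults: 100 Adam steps at lr 0.05, λ_edge = 0.005,
λ_feature = 1.0, entropy weights 0.1, all exposed.

The hard module is extracted greedily: starting from the query, repeatedly
add the highest-mask edge adjacent to the connected component built so far
(ties by the lexicographically smallest gene pair) until 20 edges are kept
or the frontier is exhausted. The result is always connected, contains the
query, has ≤ 20 edges, and lies within the two-hop region. On small graphs
where the budget exceeds the edge count, this provably matches an
exhaustive search over connected subgraphs (the tests verify it). Numeric
edge/feature thresholds for hard subgraph binarization are intentionally
not exposed as magic constants; the budgeted connected-greedy selection
plays that role.

Per-gene feature importance is the query's final feature-mask vector. A
feature scoring at least ten times the minimum *positive* score is a
representative feature (RF); the minimum is taken over positive scores to
avoid a zero denominator, and the ×10 boundary is inclusive.

## Module statistics

* **Participation**: for each gene, the number of (filtered) modules whose
  gene set contains it, excluding its own query module.
* **Hubs**: genes in strictly more than 20 modules.
* **Candidates**: per sample, the top `floor(0.10 · n)` unknown genes by
  score (ties by gene id for exact, reproducible set sizes); "shared"
  candidates are the intersection across samples.
* **Key neighbor**: the one-hop neighbor of the query whose removal
  disconnects the most genes that were reachable from the query before the
  removal (at least one; ties by gene id) — an articulation-style notion of
  the module's center. (Neighbor, query) pairs conserved in a strict
  majority of samples (> n/2) are reported.
* **Topology**: transitivity, mean clustering, degree centrality
  (normalized by n−1) and unnormalized betweenness on the module subgraph;
  singleton modules return zeros by convention.
* **Clustering**: seeded k-means (k = 5) over per-gene importance profiles.

## Synthetic data

The generator emulates the statistical shape of the real inputs with a
planted, tunable label signal; it is how every pipeline stage is tested
without external downloads.

Genes (default 2000; 200 positive / 600 negative labels, the rest unknown)
are laid head-to-tail on 4 chromosomes — lognormal lengths around 20 kb,
intergenic gaps ≥ 2 kb so promoter windows never overlap — and grouped into
20 contiguous communities. Planted effects, all seeded and recorded in a
truth file:

* `snv_effect` (default 2): positive genes' latent SNV rate is shifted by
  that many SDs of the background rate distribution (N(0.06, 0.02) on the
  magnified scale); per-sample counts are Poisson around the rate, 50
  samples. CNV is label-neutral noise (N(2, 0.5) per sample) — no CNV
  effect knob is defined.
* `track_effect` (default 1): promoter signal (Gamma(2,1) baseline) shifted
  by that many SDs for positives, independently per replicate track.
* `edge_enrichment` (default 4): extra PPI edges among positives on top of
  a community stochastic-block graph (mean within-degree 6, between-degree
  2; a scale-free option exists); kept edges get confidence in [0.5, 1),
  plus ~5 % decoy edges below 0.5 that the loader must drop.
* `hic_block_strength` (default 1): positives are preferentially placed in
  a quarter of the communities, and same-community bin pairs get a
  proportional contact boost over the power-law (exponent −1) distance
  decay with Poisson noise; resolution 25 kb.

These defaults are the strong-signal study condition; a null configuration
(all effects zero, enrichment 1) serves as the calibration control, where
test AUPRC should sit at class prevalence.

What the generator does **not** emulate: realistic mutational signatures,
chromatin-state grammar, CPDB-like PPI degree distributions, TADs/loops, or
inter-gene correlation structure beyond the community blocks. Passing tests
therefore demonstrate that the pipeline recovers planted signal of the
modeled kinds at the stated strengths — not performance on real cancer
data.

## Problem sizes and numerical choices

The test suite runs the full strong-signal condition (2000 genes, 10-fold
CV) with a 150-epoch cap per fold; smaller calibration studies (null
signal, effect monotonicity, transfer) use 400–800 genes with single
models and 60–120 epochs — sizes chosen so each study completes in seconds
to a few minutes on one CPU while keeping the planted effects well above
their standard errors. ICE tolerance 1e-5; symmetry checks at 1e-9;
SVD reconstruction tolerance 1e-8; all randomness flows from explicit
integer seeds (numpy `default_rng`), and identical seed + config reproduces
byte-identical artifacts.

## Known limitations

* Full-batch training holds the whole graph in memory; ~10⁵ nodes is the
  practical ceiling of the numpy engine.
* The explainer explains one query at a time; batch explanation is a loop.
* Contact matrices are read from sparse-TSV + bins-BED only.
* Fold-level hyperparameter search is deliberately absent; defaults are
  fixed and exposed in the configs.
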