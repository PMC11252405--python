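# oncomod

Graph-attention cancer gene prediction and gene-module dissection from
multi-omics data.

Cancer phenotypes rarely trace back to one gene; they emerge from small
interacting sets of genes — gene modules — whose members are perturbed
through different routes (mutation, copy number, chromatin state, 3D genome
organization). `oncomod` is aimed at computational cancer biologists who
want both a ranked list of likely cancer genes and, for each gene, an
interpretable account of *which interactions and which omics layers* drive
its prediction.

## What it does

1. **Feature engineering.** Per-gene features are assembled from standard
   inputs: promoter signal densities (TSS ± 1 kb) for ATAC, CTCF, H3K4me3
   and H3K27ac tracks; SNV frequency
   `x_i = 1000 · Σ_s v_si / (|S|·len_i)` (non-silent, length-normalized,
   sample-averaged); CNV frequency `Σ_s v_si / |S|`; and five Hi-C
   coordinates obtained by ICE-balancing the contact matrix, mapping bins
   to genes (`c_ij = Σ_a Σ_b h_ab` over the two genes' bin ranges) and
   taking a truncated SVD, `x_i^HiC = (U_k Σ_k)[i]`. Cell-line mode has 15
   feature columns, patient mode (no SNV/CNV) has 8.
2. **Classification.** A semi-supervised graph-transformer network over the
   PPI graph: two multi-head attention convolutions
   `x'_i = W1 x_i + Σ_j α_ij W2 x_j` with
   `α_ij = softmax_j((W3 x_i)ᵀ(W4 x_j)/√d)`, layer norm, a residual
   concatenation of the raw features into the second layer, max-pooling to
   32 dims, and a small MLP head with sigmoid output. Training uses a
   linear learning-rate warm-up (0 → 0.005 over the first 20 % of steps),
   50 % negative downsampling, early stopping on validation AUPRC
   (patience 100), tenfold cross-validation, and score averaging over the
   10 fold models. A pretrain/fine-tune path supports transfer to tasks
   with few labels.
3. **Explanation.** A mask-learning explainer attaches learnable [0, 1]
   masks to the edges and feature columns of a query gene's two-hop
   subgraph and optimizes them to preserve the prediction while being
   sparse. The resulting **gene module** is the connected, ≤ 2-hop,
   ≤ 20-edge subgraph of highest-mask interactions, plus per-feature
   importance scores; features scoring ≥ 10× the minimum are the gene's
   representative features (RFs).
4. **Module statistics.** Participation counts, hub genes (> 20 modules),
   per-sample top-10 % candidate genes and their cross-sample
   intersection, conserved (key neighbor, query) pairs, topology metrics,
   and k-means clustering of importance profiles.

A seeded synthetic-data generator emulates every input format with planted
label signal, so the full pipeline is testable offline.

The model and explainer run on a small numpy autodiff engine included in
the package — no deep-learning framework is needed.

## Worked example

```python
import pandas as pd
from oncomod import (SyntheticConfig, generate, make_splits, train_cv,
                     ensemble_predict, evaluate, TrainConfig, GNNMaskExplainer)
from oncomod.pipeline import build_graph

cfg = SyntheticConfig(n_genes=600, n_positive=60, n_negative=180, seed=7)
graph = build_graph(generate(cfg))            # 15-dim features on PPI edges

splits = make_splits(pd.Series(graph.y, index=graph.gene_ids), seed=7)
models, logs = train_cv(graph, splits, train_cfg=TrainConfig(max_epochs=80, seed=7))
preds = ensemble_predict(models, graph, genes=splits.test_genes)
report = evaluate(preds["score"].to_numpy(), preds["label"].to_numpy())
print(report)

query = preds.sort_values("score", ascending=False)["gene_id"].iloc[0]
module = GNNMaskExplainer(models[0].net_).explain(graph, query, seed=7)
print(query, len(module.genes), len(module.edges), module.rf_set)
```

Output:

```
MetricsReport(auprc=0.9716666666666667, auroc=0.9896296296296296, accuracy=0.9333333333333333, f1=0.875)
g00179 21 20 [0, 2, 4, 6, 9]
```

The ensemble separates the held-out labeled genes almost perfectly (AUPRC
0.97 at 25 % prevalence — the generator's default planted signal is
strong). The module for the top-scoring test gene `g00179` is a connected
21-gene, 20-edge interaction neighborhood; the RF list names the feature
columns (in the 15-column layout: ATAC, a CTCF replicate, an H3K4me3
replicate, an H3K27ac replicate and SNV) whose importance is at least
tenfold the minimum — the omics layers the model leaned on for this gene.

Exact numbers above are for this seed and configuration; other seeds give
similar magnitudes.

## Command line

```bash
oncomod all --workspace ws --config config.yaml --seed 1
```

runs simulate → features → graph → train → predict → explain → analyze
into a workspace, writing predictions, metrics, per-gene module JSON and
the module statistics tables, with content-hash caching so unchanged
stages are skipped on re-runs. Individual stage subcommands take the same
flags.

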