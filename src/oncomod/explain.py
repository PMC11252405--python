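"""Mask-learning explanation of per-gene predictions ("gene modules").

For a query gene, the explainer restricts attention to the exact 2-hop
computation subgraph (all nodes whose features can influence a two-layer
model's output at the query), attaches a learnable mask value in [0, 1] to
every undirected edge and to every input feature, and optimizes the masks by
gradient descent so that the masked prediction stays close to the model's
original prediction while the masks are pushed to be sparse and binary
(mask-sum and mask-entropy penalties).  Maximizing the mutual information
between the prediction and a small (subgraph, feature-subset) pair is not
directly computable; this masked-prediction cross-entropy surrogate is the
standard relaxation.

Edge masks live on undirected edges and are applied to both message
directions, so symmetry holds by construction at every step.  Setting every
mask to 1 reproduces the model's original prediction exactly.

The final hard module is extracted greedily: starting from the query,
repeatedly add the highest-mask edge adjacent to the connected component
built so far (ties broken by the lexicographic (gene_a, gene_b) pair), up to
``max_edges`` (default 20).  The result is a connected subgraph containing
the query, confined to the 2-hop region.  A feature whose importance is at
least ten times the minimum positive importance is flagged as a
representative feature (RF) of the gene.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from ._autodiff import Adam, Tensor, gather_rows
from .graph import MultiOmicsGraph

__all__ = [
    "ExplanationMasks",
    "GeneModule",
    "GNNMaskExplainer",
    "learn_masks",
    "extract_module",
    "representative_features",
    "rf_blocks",
    "stability_check",
]

RF_FOLD = 10.0


@dataclass
class ExplanationMasks:
    query_gene: str
    nodes: list[str]  # the 2-hop computation subgraph, sorted
    edges: list[tuple[str, str]]  # undirected, within the subgraph
    edge_mask: np.ndarray  # per undirected edge, in [0, 1]
    feature_mask: np.ndarray  # per feature, in [0, 1]
    original_prob: float
    seed: int

    def __post_init__(self):
        if ((self.edge_mask < 0) | (self.edge_mask > 1)).any():
            raise ValueError("edge mask values must be in [0, 1]")
        if ((self.feature_mask < 0) | (self.feature_mask > 1)).any():
            raise ValueError("feature mask values must be in [0, 1]")


@dataclass
class GeneModule:
    query_gene: str
    genes: list[str]
    edges: list[tuple[str, str]]
    feature_importance: np.ndarray
    rf_set: list[int] = field(default_factory=list)
    run_id: str = ""

    def to_json(self) -> str:
        return json.dumps({
            "query": self.query_gene,
            "genes": self.genes,
            "edges": [list(e) for e in self.edges],
            "feature_importance": np.asarray(self.feature_importance).tolist(),
            "rf": self.rf_set,
            "run_id": self.run_id,
        })

    @classmethod
    def from_json(cls, text: str) -> "GeneModule":
        d = json.loads(text)
        return cls(
            query_gene=d["query"], genes=d["genes"],
            edges=[tuple(e) for e in d["edges"]],
            feature_importance=np.array(d["feature_importance"]),
            rf_set=d["rf"], run_id=d.get("run_id", ""),
        )


def _two_hop_subgraph(graph: MultiOmicsGraph, query: str):
    """Sorted 2-hop node list, induced undirected edges, local edge index."""
    adj: dict[str, set[str]] = {g: set() for g in graph.gene_ids}
    for a, b in graph.edges:
        adj[a].add(b)
        adj[b].add(a)
    one = adj[query]
    two = set().union(*(adj[n] for n in one)) if one else set()
    nodes = sorted({query} | one | two)
    pos = {g: i for i, g in enumerate(nodes)}
    edges = [(a, b) for a, b in graph.edges if a in pos and b in pos]
    if edges:
        und = np.array([[pos[a], pos[b]] for a, b in edges], dtype=np.intp)
        edge_index = np.hstack([und.T, und.T[::-1]])
        # map each directed edge back to its undirected mask slot
        dir_to_und = np.concatenate([np.arange(len(edges))] * 2)
    else:
        edge_index = np.zeros((2, 0), dtype=np.intp)
        dir_to_und = np.zeros(0, dtype=np.intp)
    return nodes, edges, edge_index, dir_to_und, pos


def _mask_entropy(m: Tensor) -> Tensor:
    eps = 1e-12
    return -(m * (m + eps).log() + (1.0 - m) * (1.0 - m + eps).log()).mean()


class GNNMaskExplainer:
    """Learns edge/feature masks explaining one node's prediction.

    ``model`` must expose ``forward(X, edge_index, edge_mask=..., feature_mask=...)``
    returning per-node probabilities as an autodiff tensor — the package's
    :class:`~oncomod.net.GraphTransformerNet` does, and so can any hand-built
    stand-in with the same protocol.
    """

    def __init__(
        self,
        model,
        epochs: int = 100,
        lr: float = 0.05,
        lambda_edge: float = 0.005,
        lambda_edge_entropy: float = 0.1,
        lambda_feature: float = 1.0,
        lambda_feature_entropy: float = 0.1,
    ):
        self.model = model
        self.epochs = epochs
        self.lr = lr
        self.lambda_edge = lambda_edge
        self.lambda_edge_entropy = lambda_edge_entropy
        self.lambda_feature = lambda_feature
        self.lambda_feature_entropy = lambda_feature_entropy

    def learn_masks(
        self, graph: MultiOmicsGraph, query: str, seed: int = 0
    ) -> ExplanationMasks:
        if query not in graph.gene_ids:
            raise KeyError(f"unknown gene: {query}")
        nodes, edges, edge_index, dir_to_und, pos = _two_hop_subgraph(graph, query)
        Xs = graph.X[[graph.index_of(g) for g in nodes]]
        q_local = pos[query]
        p0 = float(self.model.forward(Xs, edge_index).data[q_local])
        if not np.isfinite(p0):
            raise ValueError("model produced a non-finite prediction")
        target = 1.0 if p0 >= 0.5 else 0.0

        rng = np.random.default_rng(seed)
        n_feat = Xs.shape[1]
        edge_logits = Tensor(rng.normal(1.0, 0.1, size=len(edges)), requires_grad=True)
        feat_logits = Tensor(rng.normal(1.0, 0.1, size=n_feat), requires_grad=True)
        opt = Adam([edge_logits, feat_logits], lr=self.lr)
        for _ in range(self.epochs):
            edge_mask_u = edge_logits.sigmoid()
            feat_mask = feat_logits.sigmoid()
            kwargs = {"feature_mask": feat_mask}
            if len(edges):
                kwargs["edge_mask"] = gather_rows(
                    edge_mask_u.reshape(-1, 1), dir_to_und
                ).reshape(-1)
            # Work on the pre-sigmoid output when the model exposes it: for a
            # well-trained (saturated) model the cross-entropy gradient
            # vanishes, while the logit keeps a usable gradient signal.
            if hasattr(self.model, "logits"):
                z = self.model.logits(Xs, edge_index, **kwargs)[q_local]
                pred_loss = -z if target == 1.0 else z
            else:
                p = self.model.forward(Xs, edge_index, **kwargs)[q_local]
                eps = 1e-12
                if target == 1.0:
                    pred_loss = -(p + eps).log()
                else:
                    pred_loss = -(1.0 - p + eps).log()
            loss = pred_loss + self.lambda_feature * feat_mask.mean() \
                + self.lambda_feature_entropy * _mask_entropy(feat_mask)
            if len(edges):
                loss = loss + self.lambda_edge * edge_mask_u.sum() \
                    + self.lambda_edge_entropy * _mask_entropy(edge_mask_u)
            opt.zero_grad()
            loss.backward()
            opt.step()
        return ExplanationMasks(
            query_gene=query,
            nodes=nodes,
            edges=edges,
            edge_mask=1.0 / (1.0 + np.exp(-edge_logits.data)),
            feature_mask=1.0 / (1.0 + np.exp(-feat_logits.data)),
            original_prob=p0,
            seed=seed,
        )

    def explain(
        self, graph: MultiOmicsGraph, query: str, seed: int = 0,
        max_edges: int = 20,
    ) -> GeneModule:
        masks = self.learn_masks(graph, query, seed=seed)
        return extract_module(masks, max_edges=max_edges)


def learn_masks(
    model, graph: MultiOmicsGraph, query: str,
    epochs: int = 100, lr: float = 0.05, seed: int = 0,
) -> ExplanationMasks:
    return GNNMaskExplainer(model, epochs=epochs, lr=lr).learn_masks(
        graph, query, seed=seed
    )


def extract_module(
    masks: ExplanationMasks, max_edges: int = 20, max_hops: int = 2
) -> GeneModule:
    """Greedy connected module: repeatedly take the highest-mask frontier edge.

    Starting from the query's singleton component, the undirected edge with
    the largest mask value among those touching the component is added (ties
    broken by the lexicographically smallest (gene_a, gene_b) pair) until
    ``max_edges`` edges are kept or the frontier is empty.  Nodes of the
    computation subgraph are within ``max_hops`` of the query by
    construction, so every module gene is too.
    """
    ranked = sorted(
        zip(masks.edge_mask, masks.edges), key=lambda t: (-t[0], t[1])
    )
    component = {masks.query_gene}
    kept: list[tuple[str, str]] = []
    remaining = list(ranked)
    while remaining and len(kept) < max_edges:
        pick = None
        for i, (_, (a, b)) in enumerate(remaining):
            if a in component or b in component:
                pick = i
                break
        if pick is None:
            break
        _, (a, b) = remaining.pop(pick)
        kept.append((a, b))
        component.update((a, b))
    importance = np.asarray(masks.feature_mask, dtype=np.float64)
    rf = representative_features(importance)
    return GeneModule(
        query_gene=masks.query_gene,
        genes=sorted(component),
        edges=kept,
        feature_importance=importance,
        rf_set=rf,
        run_id=f"seed{masks.seed}",
    )


def representative_features(
    feature_importance: np.ndarray, fold: float = RF_FOLD
) -> list[int]:
    """Indices of features scoring at least ``fold`` x the minimum positive score."""
    scores = np.asarray(feature_importance, dtype=np.float64)
    if scores.size < 2:
        raise ValueError("need at least two feature scores")
    if (scores < 0).any():
        raise ValueError("importance scores must be >= 0")
    positive = scores[scores > 0]
    if positive.size == 0:
        warnings.warn("all importance scores are zero; no representative features")
        return []
    cutoff = fold * positive.min()
    return [int(i) for i in np.flatnonzero(scores >= cutoff)]


def rf_blocks(
    feature_importance: np.ndarray, block_widths: dict[str, int],
    fold: float = RF_FOLD,
) -> list[str]:
    """Representative features grouped to named omics blocks (max within block)."""
    scores = np.asarray(feature_importance, dtype=np.float64)
    rf = set(representative_features(scores, fold=fold))
    names = []
    offset = 0
    for name, width in block_widths.items():
        if rf & set(range(offset, offset + width)):
            names.append(name)
        offset += width
    return names


def stability_check(
    model, graph: MultiOmicsGraph, query: str, seed_list: list[int],
    epochs: int = 100, lr: float = 0.05, max_edges: int = 20,
) -> float:
    """Mean pairwise Jaccard similarity of module gene sets across repeats."""
    if len(seed_list) < 2:
        raise ValueError("need at least two repeats")
    explainer = GNNMaskExplainer(model, epochs=epochs, lr=lr)
    gene_sets = [
        set(explainer.explain(graph, query, seed=s, max_edges=max_edges).genes)
        for s in seed_list
    ]
    sims = [
        len(a & b) / len(a | b) if (a | b) else 1.0
        for a, b in combinations(gene_sets, 2)
    ]
    return float(np.mean(sims))
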