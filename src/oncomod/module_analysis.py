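"""Statistics over collections of gene modules.

Given the per-query modules produced by the explainer (per cell line or per
patient), this module computes: how often each gene participates in other
genes' modules, which genes are hubs (strictly more than 20 participations),
which unknown genes rank in the top 10% of prediction scores per sample and
are shared across all samples ("candidate" genes), which (key neighbor,
query) pairs recur in a strict majority of samples, standard topology
metrics of a module subgraph, and a k-means clustering of per-gene feature
importance profiles.

The "key neighbor" of a query's module is the one-hop neighbor of the query
whose removal disconnects the largest number of remaining module genes from
the query (at least one; ties broken by gene id) — the articulation-style
center through which the query reaches the rest of its module.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.cluster import KMeans

from .explain import GeneModule

__all__ = [
    "ModuleCollection",
    "CandidateGeneSet",
    "participation_counts",
    "hub_genes",
    "candidate_genes",
    "neighbor_cancer_pairs",
    "topology_metrics",
    "cluster_feature_importance",
]

HUB_THRESHOLD = 20
TOP_FRACTION = 0.10


@dataclass
class ModuleCollection:
    modules: list[GeneModule]
    sample_id: str = "sample"

    def __post_init__(self):
        queries = [m.query_gene for m in self.modules]
        if len(queries) != len(set(queries)):
            raise ValueError("duplicate query genes within a sample")


@dataclass
class CandidateGeneSet:
    per_sample_top: dict[str, list[str]]
    shared: list[str]
    top_fraction: float = TOP_FRACTION


def participation_counts(
    collection: ModuleCollection, query_filter=None
) -> dict[str, int]:
    """Number of modules each gene appears in, excluding its own query module.

    ``query_filter`` restricts which modules count: a container of query
    genes or a predicate on the query gene (e.g. known cancer genes only).
    """
    if query_filter is None:
        selected = collection.modules
    elif callable(query_filter):
        selected = [m for m in collection.modules if query_filter(m.query_gene)]
    else:
        allowed = set(query_filter)
        selected = [m for m in collection.modules if m.query_gene in allowed]
    counts: Counter[str] = Counter()
    for module in selected:
        for gene in module.genes:
            if gene != module.query_gene:
                counts[gene] += 1
    return dict(counts)


def hub_genes(counts: dict[str, int], threshold: int = HUB_THRESHOLD) -> set[str]:
    """Genes participating in strictly more than ``threshold`` modules."""
    return {g for g, c in counts.items() if c > threshold}


def candidate_genes(
    scores: dict[str, dict[str, float]], top_fraction: float = TOP_FRACTION
) -> CandidateGeneSet:
    """Per-sample top-fraction of unknown-gene scores, intersected across samples.

    ``scores`` maps sample -> {gene: prediction score} over unknown-label
    genes only.  Each sample reserves exactly ``floor(fraction * n)`` genes
    (score descending, ties by gene id ascending); ``shared`` is the
    intersection over all samples, sorted.
    """
    if not scores or any(not s for s in scores.values()):
        raise ValueError("empty score map")
    per_sample: dict[str, list[str]] = {}
    for sample, gene_scores in scores.items():
        n_keep = int(np.floor(top_fraction * len(gene_scores)))
        ranked = sorted(gene_scores.items(), key=lambda kv: (-kv[1], kv[0]))
        per_sample[sample] = [g for g, _ in ranked[:n_keep]]
    shared = set.intersection(*(set(v) for v in per_sample.values()))
    return CandidateGeneSet(
        per_sample_top=per_sample, shared=sorted(shared), top_fraction=top_fraction
    )


def _key_neighbor(module: GeneModule) -> str | None:
    """One-hop neighbor of the query whose removal strands the most genes."""
    G = nx.Graph(module.edges)
    if module.query_gene not in G:
        return None
    q = module.query_gene
    baseline = nx.node_connected_component(G, q)  # reachable before removal
    best_gene, best_cut = None, 0
    for n in sorted(G.neighbors(q)):
        H = G.copy()
        H.remove_node(n)
        reachable = nx.node_connected_component(H, q) if q in H else set()
        stranded = len(baseline - reachable - {n})
        if stranded > best_cut:
            best_gene, best_cut = n, stranded
    return best_gene if best_cut >= 1 else None


def neighbor_cancer_pairs(
    collections: list[ModuleCollection], min_samples: int | None = None
) -> list[dict]:
    """(key neighbor, query) pairs conserved in at least ``min_samples`` samples.

    Default ``min_samples`` is a strict majority, ``n_samples // 2 + 1``.
    Returns records sorted by descending sample count then pair.
    """
    n_samples = len(collections)
    if min_samples is None:
        min_samples = n_samples // 2 + 1
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    pair_samples: dict[tuple[str, str], set[str]] = {}
    for coll in collections:
        for module in coll.modules:
            neighbor = _key_neighbor(module)
            if neighbor is None:
                continue
            pair_samples.setdefault((neighbor, module.query_gene), set()).add(
                coll.sample_id
            )
    records = [
        {"neighbor": n, "query": q, "n_samples": len(samples),
         "samples": sorted(samples)}
        for (n, q), samples in pair_samples.items()
        if len(samples) >= min_samples
    ]
    records.sort(key=lambda r: (-r["n_samples"], r["neighbor"], r["query"]))
    return records


def topology_metrics(module: GeneModule) -> dict:
    """Transitivity, mean clustering, degree and betweenness centralities.

    Betweenness is unnormalized shortest-path counts; a singleton module
    returns zeros by convention.
    """
    G = nx.Graph()
    G.add_nodes_from(module.genes)
    G.add_edges_from(module.edges)
    if G.number_of_nodes() <= 1:
        genes = list(G.nodes)
        return {
            "transitivity": 0.0, "mean_clustering": 0.0,
            "degree_centrality": {g: 0.0 for g in genes},
            "betweenness_centrality": {g: 0.0 for g in genes},
        }
    return {
        "transitivity": float(nx.transitivity(G)),
        "mean_clustering": float(nx.average_clustering(G)),
        "degree_centrality": nx.degree_centrality(G),
        "betweenness_centrality": nx.betweenness_centrality(G, normalized=False),
    }


def cluster_feature_importance(
    importance_matrix: np.ndarray, k: int = 5, seed: int = 0
) -> np.ndarray:
    """Seeded k-means over per-gene feature-importance profiles."""
    X = np.asarray(importance_matrix, dtype=np.float64)
    if len(np.unique(X, axis=0)) < k:
        raise ValueError(f"need at least {k} distinct importance rows")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(X)
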