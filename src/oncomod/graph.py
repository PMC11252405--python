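"""Multi-omics graph assembly: PPI edges, feature concatenation, labels, splits.

The working object is :class:`MultiOmicsGraph`: genes as nodes, confidence-
filtered protein-protein interactions as undirected edges, a concatenated
feature matrix ``X`` (15 columns in cell-line mode, 8 in patient mode), and
tri-state labels (1 = known cancer gene, 0 = confident non-cancer gene,
-1 = unknown).  Training is semi-supervised: unknown genes contribute
features and topology, never loss.

Feature block layout (column order is fixed):

====================  ==================  =================
block                 cell-line mode      patient mode
====================  ==================  =================
ATAC                  1                   1
CTCF                  3 (replicates)      1
H3K4me3               2 (replicates)      --
H3K27ac               2 (replicates)      1
CNV                   1                   --
SNV                   1                   --
Hi-C (SVD)            5                   5
====================  ==================  =================
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

__all__ = [
    "MultiOmicsGraph",
    "SplitPlan",
    "NeighborSubgraph",
    "BLOCK_LAYOUTS",
    "load_ppi",
    "read_labels",
    "condense_network",
    "assemble_features",
    "make_splits",
    "sample_subgraph",
]

BLOCK_LAYOUTS: dict[str, dict[str, int]] = {
    "cell_line": {
        "ATAC": 1, "CTCF": 3, "H3K4me3": 2, "H3K27ac": 2,
        "CNV": 1, "SNV": 1, "HiC": 5,
    },
    "patient": {"ATAC": 1, "CTCF": 1, "H3K27ac": 1, "HiC": 5},
}

DEFAULT_PPI_THRESHOLD = 0.5


@dataclass
class MultiOmicsGraph:
    """Genes + PPI edges + feature matrix + tri-state labels."""

    gene_ids: list[str]
    edges: list[tuple[str, str]]
    X: np.ndarray
    y: np.ndarray  # per-gene label in {1, 0, -1}
    mode: str = "cell_line"
    block_widths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.shape[0] != len(self.gene_ids):
            raise ValueError("X row count must equal number of genes")
        if self.y.shape[0] != len(self.gene_ids):
            raise ValueError("label count must equal number of genes")
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        seen = set()
        clean = []
        for a, b in self.edges:
            if a == b or a not in idx or b not in idx:
                raise ValueError(f"invalid edge ({a}, {b})")
            key = (a, b) if a <= b else (b, a)
            if key not in seen:
                seen.add(key)
                clean.append(key)
        self.edges = clean
        self._index = idx

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def edge_index(self) -> np.ndarray:
        """Directed edge index (2, 2|E|): both directions of every edge."""
        if not self.edges:
            return np.zeros((2, 0), dtype=np.intp)
        pairs = np.array(
            [[self._index[a], self._index[b]] for a, b in self.edges], dtype=np.intp
        )
        return np.hstack([pairs.T, pairs.T[::-1]])

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.gene_ids)
        G.add_edges_from(self.edges)
        return G

    # -- serialization -------------------------------------------------------
    def save(self, prefix: str) -> None:
        pd.DataFrame(self.edges, columns=["gene_a", "gene_b"]).to_csv(
            f"{prefix}.edges.tsv", sep="\t", index=False
        )
        pd.DataFrame(self.X, index=self.gene_ids).to_csv(
            f"{prefix}.features.tsv", sep="\t", header=False
        )
        pd.DataFrame({"gene_id": self.gene_ids, "label": self.y}).to_csv(
            f"{prefix}.labels.tsv", sep="\t", index=False
        )
        with open(f"{prefix}.meta.json", "w") as fh:
            json.dump({"mode": self.mode, "block_widths": self.block_widths}, fh)

    @classmethod
    def load(cls, prefix: str) -> "MultiOmicsGraph":
        edges_df = pd.read_csv(f"{prefix}.edges.tsv", sep="\t", dtype=str)
        feats = pd.read_csv(f"{prefix}.features.tsv", sep="\t", header=None, index_col=0)
        labels = pd.read_csv(f"{prefix}.labels.tsv", sep="\t", dtype={"gene_id": str})
        with open(f"{prefix}.meta.json") as fh:
            meta = json.load(fh)
        gene_ids = [str(g) for g in feats.index]
        y = labels.set_index("gene_id")["label"].reindex(gene_ids).to_numpy()
        return cls(
            gene_ids=gene_ids,
            edges=list(edges_df.itertuples(index=False, name=None)),
            X=feats.to_numpy(),
            y=y,
            mode=meta["mode"],
            block_widths=meta["block_widths"],
        )


@dataclass
class SplitPlan:
    """Stratified test split + tenfold CV partition of the training genes."""

    test_genes: list[str]
    folds: list[list[str]]  # validation gene lists, one per fold
    seed: int

    @property
    def train_genes(self) -> list[str]:
        return [g for fold in self.folds for g in fold]


@dataclass
class NeighborSubgraph:
    """Exact <=2-hop neighborhood of a center gene with induced edges."""

    center_gene: str
    nodes: list[str]
    edges: list[tuple[str, str]]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def load_ppi(
    edge_table, score_threshold: float = DEFAULT_PPI_THRESHOLD
) -> list[tuple[str, str]]:
    """Read (gene_a, gene_b, score) rows; keep score >= threshold.

    Symmetrizes, deduplicates, drops self-loops; malformed rows are skipped
    and counted in the log.  Accepts a path or a DataFrame.
    """
    if not isinstance(edge_table, pd.DataFrame):
        edge_table = pd.read_csv(
            edge_table, sep="\t", header=None, names=["gene_a", "gene_b", "score"],
            dtype={"gene_a": str, "gene_b": str},
        )
    edges: set[tuple[str, str]] = set()
    skipped = 0
    for a, b, score in edge_table.itertuples(index=False, name=None):
        try:
            score = float(score)
        except (TypeError, ValueError):
            skipped += 1
            continue
        if pd.isna(a) or pd.isna(b) or not np.isfinite(score):
            skipped += 1
            continue
        if a == b or score < score_threshold:
            continue
        edges.add((a, b) if a <= b else (b, a))
    if skipped:
        logger.warning("load_ppi: skipped %d malformed rows", skipped)
    return sorted(edges)


def read_labels(path) -> pd.DataFrame:
    """TSV with header (gene_id, label), label in {1, 0, -1}."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not set(df["label"]).issubset({1, 0, -1}):
        raise ValueError("labels must be in {1, 0, -1}")
    return df


def condense_network(graph: MultiOmicsGraph) -> MultiOmicsGraph:
    """Drop degree-0 genes (features/labels subset accordingly)."""
    degree = {g: 0 for g in graph.gene_ids}
    for a, b in graph.edges:
        degree[a] += 1
        degree[b] += 1
    keep = [g for g in graph.gene_ids if degree[g] > 0]
    if not keep:
        raise ValueError("condensed graph is empty")
    if len(keep) == len(graph.gene_ids):
        return graph
    keep_idx = [graph.index_of(g) for g in keep]
    return MultiOmicsGraph(
        gene_ids=keep,
        edges=graph.edges,
        X=graph.X[keep_idx],
        y=graph.y[keep_idx],
        mode=graph.mode,
        block_widths=graph.block_widths,
    )


def assemble_features(
    blocks: dict[str, np.ndarray],
    mode: str = "cell_line",
    normalize: bool = True,
) -> np.ndarray:
    """Concatenate per-gene feature blocks in the fixed layout order.

    Each block value is (n_genes, width) or (n_genes,) for width 1.  With
    ``normalize`` every column is z-scored over all genes (zero-variance
    columns map to 0).
    """
    layout = BLOCK_LAYOUTS[mode]
    missing = [name for name in layout if name not in blocks]
    if missing:
        raise ValueError(f"missing feature blocks for mode {mode!r}: {missing}")
    cols = []
    n_genes = None
    for name, width in layout.items():
        arr = np.atleast_2d(np.asarray(blocks[name], dtype=np.float64))
        if arr.shape[0] == 1 and width == 1:
            arr = arr.T
        if arr.shape[1] != width:
            raise ValueError(
                f"block {name!r} has {arr.shape[1]} columns, expected {width}"
            )
        if n_genes is None:
            n_genes = arr.shape[0]
        elif arr.shape[0] != n_genes:
            raise ValueError(f"block {name!r} gene count mismatch")
        cols.append(arr)
    X = np.hstack(cols)
    if normalize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        X = (X - mu) / sd_safe
        X[:, sd == 0] = 0.0
    return X


def make_splits(
    labels: dict[str, int] | pd.Series,
    seed: int = 42,
    test_fraction: float = 0.25,
    n_folds: int = 10,
) -> SplitPlan:
    """Stratified 25% test split and tenfold CV partition of the rest.

    Folds are built by dealing each class's shuffled members round-robin, so
    per-fold label counts stay within one gene of the global ratio even when
    a class has fewer members than folds.
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    labeled = labels[labels.isin([0, 1])]
    genes = np.array(sorted(labeled.index))
    y = labeled.reindex(genes).to_numpy()
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 labeled genes of each class")
    train_g, test_g, y_train, _ = train_test_split(
        genes, y, test_size=test_fraction, stratify=y, random_state=seed
    )
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for cls in (1, 0):
        members = np.sort(train_g[y_train == cls])
        members = members[rng.permutation(len(members))]
        for i, gene in enumerate(members):
            folds[i % n_folds].append(gene)
    return SplitPlan(test_genes=sorted(test_g), folds=[sorted(f) for f in folds],
                     seed=seed)


def sample_subgraph(graph: MultiOmicsGraph, center: str) -> NeighborSubgraph:
    """All first- and second-order neighbors of ``center`` with induced edges."""
    if center not in graph._index:
        raise KeyError(f"unknown gene: {center}")
    adj: dict[str, set[str]] = {}
    for a, b in graph.edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    one_hop = adj.get(center, set())
    two_hop = set()
    for n in one_hop:
        two_hop |= adj.get(n, set())
    nodes = {center} | one_hop | two_hop
    node_list = sorted(nodes)
    induced = [(a, b) for a, b in graph.edges if a in nodes and b in nodes]
    return NeighborSubgraph(center_gene=center, nodes=node_list, edges=induced)
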