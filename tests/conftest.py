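"""Shared fixtures: toy inputs, small synthetic datasets, a trained model.

Expensive fixtures are session-scoped so the training-dependent tests share
one fitted model instead of re-training per test.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

# make `tests.*` cross-imports work regardless of the invocation directory
sys.path.insert(0, str(Path(__file__).resolve().parent.parent))

from oncomod.pipeline import build_graph
from oncomod.synthetic import SyntheticConfig, generate, toy_fixtures
from oncomod.train import GraphTransformerClassifier


@pytest.fixture(scope="session")
def toy():
    return toy_fixtures()


@pytest.fixture(scope="session")
def small_dataset():
    """A small dataset with all planted signals at their defaults."""
    cfg = SyntheticConfig(n_genes=600, n_positive=60, n_negative=180, seed=1)
    return generate(cfg)


@pytest.fixture(scope="session")
def small_graph(small_dataset):
    return build_graph(small_dataset)


@pytest.fixture(scope="session")
def snv_only_graph():
    """Graph whose only planted label signal is the SNV mutation rate."""
    cfg = SyntheticConfig(
        n_genes=600, n_positive=60, n_negative=180, seed=1,
        snv_effect=3.0, track_effect=0.0, hic_block_strength=0.0,
        edge_enrichment=1.0,
    )
    return build_graph(generate(cfg))


@pytest.fixture(scope="session")
def trained_snv_model(snv_only_graph):
    """Classifier fitted on the SNV-only graph (shared across tests)."""
    from oncomod.graph import make_splits

    g = snv_only_graph
    labels = pd.Series(g.y, index=g.gene_ids)
    plan = make_splits(labels, seed=0)
    val = [x for fold in plan.folds[:2] for x in fold]
    train = [x for fold in plan.folds[2:] for x in fold]
    clf = GraphTransformerClassifier(max_epochs=120, patience=100, random_state=0)
    clf.fit(
        g.X, g.y, edge_index=g.edge_index(),
        train_idx=np.array([g.index_of(x) for x in train]),
        val_idx=np.array([g.index_of(x) for x in val]),
    )
    return clf


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_multiomics_graph(rng, n_nodes=12, n_features=4, edge_prob=0.3):
    """Small random graph helper used by oracle-equivalence tests."""
    from oncomod.graph import MultiOmicsGraph

    gene_ids = [f"n{i:02d}" for i in range(n_nodes)]
    edges = [
        (gene_ids[i], gene_ids[j])
        for i in range(n_nodes) for j in range(i + 1, n_nodes)
        if rng.random() < edge_prob
    ]
    X = rng.normal(size=(n_nodes, n_features))
    y = rng.choice([1, 0, -1], size=n_nodes)
    return MultiOmicsGraph(gene_ids=gene_ids, edges=edges, X=X, y=y)
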