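"""Mask learning, module extraction, representative features, stability."""

import itertools

import networkx as nx
import numpy as np
import pytest

from oncomod._autodiff import Tensor
from oncomod.explain import (
    ExplanationMasks,
    GNNMaskExplainer,
    extract_module,
    representative_features,
    rf_blocks,
    stability_check,
)
from tests.conftest import random_multiomics_graph


class SingleFeatureModel:
    """Hand-built readout whose output depends on exactly one input feature."""

    def __init__(self, feature_idx, in_dim, weight=4.0):
        w = np.zeros(in_dim)
        w[feature_idx] = weight
        self.w = Tensor(w.reshape(-1, 1))

    def logits(self, X, edge_index, edge_mask=None, feature_mask=None, **kw):
        X = X if isinstance(X, Tensor) else Tensor(X)
        if feature_mask is not None:
            X = X * feature_mask
        return (X @ self.w).reshape(-1)

    def forward(self, X, edge_index, **kw):
        return self.logits(X, edge_index, **kw).sigmoid()


class ConstantModel:
    """Ignores every input; prediction is a fixed probability."""

    def logits(self, X, edge_index, edge_mask=None, feature_mask=None, **kw):
        X = X if isinstance(X, Tensor) else Tensor(X)
        if feature_mask is not None:
            X = X * feature_mask
        zero = (X * 0.0).sum(axis=1)
        if edge_mask is not None:
            zero = zero + (edge_mask * 0.0).sum()[...] * 0.0
        return zero + 0.8

    def forward(self, X, edge_index, **kw):
        return self.logits(X, edge_index, **kw).sigmoid()


def masks_from(edges, values, query="q", nodes=None, feature_mask=None):
    nodes = nodes or sorted({n for e in edges for n in e} | {query})
    return ExplanationMasks(
        query_gene=query, nodes=nodes, edges=edges,
        edge_mask=np.asarray(values, dtype=float),
        feature_mask=np.array([0.5, 0.5]) if feature_mask is None else feature_mask,
        original_prob=0.9, seed=0,
    )


class TestLearnMasks:
    def test_single_informative_feature_gets_top_mask(self, rng):
        g = random_multiomics_graph(rng, n_nodes=15, n_features=6, edge_prob=0.3)
        g.X[:, 3] = 2.0  # strong positive evidence on feature 3
        model = SingleFeatureModel(3, in_dim=6)
        ex = GNNMaskExplainer(model, epochs=80)
        masks = ex.learn_masks(g, g.gene_ids[0], seed=0)
        assert int(np.argmax(masks.feature_mask)) == 3

    def test_constant_model_leaves_prediction_and_structure_alone(self, rng):
        g = random_multiomics_graph(rng, n_nodes=10, n_features=4, edge_prob=0.3)
        model = ConstantModel()
        ex = GNNMaskExplainer(model, epochs=50)
        masks = ex.learn_masks(g, g.gene_ids[0], seed=0)
        # prediction is untouched by masking ...
        assert masks.original_prob == pytest.approx(
            1 / (1 + np.exp(-0.8)), abs=1e-9
        )
        # ... and the learned masks carry no spurious structure: the sparsity
        # penalty shifts all values together, so they stay nearly uniform
        assert np.ptp(masks.feature_mask) < 0.05
        if len(masks.edge_mask):
            assert np.ptp(masks.edge_mask) < 0.05

    def test_same_seed_identical_masks(self, trained_snv_model, snv_only_graph):
        g = snv_only_graph
        q = g.gene_ids[int(np.argmax(trained_snv_model.decision_function()))]
        ex = GNNMaskExplainer(trained_snv_model.net_, epochs=30)
        a = ex.learn_masks(g, q, seed=4)
        b = ex.learn_masks(g, q, seed=4)
        np.testing.assert_array_equal(a.edge_mask, b.edge_mask)
        np.testing.assert_array_equal(a.feature_mask, b.feature_mask)

    def test_unknown_query_errors(self, rng):
        g = random_multiomics_graph(rng, n_nodes=5)
        with pytest.raises(KeyError):
            GNNMaskExplainer(ConstantModel()).learn_masks(g, "nope")


def test_all_ones_masks_reproduce_prediction_exactly(
    trained_snv_model, snv_only_graph
):
    g = snv_only_graph
    net = trained_snv_model.net_
    ei = g.edge_index()
    base = net.predict_proba(g.X, ei)
    masked = net.forward(
        g.X, ei,
        edge_mask=Tensor(np.ones(ei.shape[1])),
        feature_mask=Tensor(np.ones(g.X.shape[1])),
    ).data
    np.testing.assert_array_equal(masked, base)


def test_edge_mask_is_symmetric_by_construction(
    trained_snv_model, snv_only_graph
):
    """One mask value per undirected edge serves both message directions."""
    g = snv_only_graph
    q = g.gene_ids[int(np.argmax(trained_snv_model.decision_function()))]
    ex = GNNMaskExplainer(trained_snv_model.net_, epochs=20)
    masks = ex.learn_masks(g, q, seed=0)
    M = {}
    for (a, b), v in zip(masks.edges, masks.edge_mask):
        M[(a, b)] = v
        M[(b, a)] = v
    for (a, b), v in list(M.items()):
        assert M[(b, a)] == v
    assert ((masks.edge_mask >= 0) & (masks.edge_mask <= 1)).all()


class TestExtractModule:
    def test_star_capped_at_20_edges(self):
        edges = [("q", f"n{i:02d}") for i in range(25)]
        module = extract_module(masks_from(edges, [0.9] * 25))
        assert len(module.edges) == 20
        assert "q" in module.genes

    def test_matches_exhaustive_search_on_small_graphs(self, rng):
        """Brute force over all edge subsets: connected, contains query,
        <= 20 edges, maximal total kept mask."""
        for trial in range(30):
            n = int(rng.integers(4, 7))
            G = nx.gnm_random_graph(n, int(rng.integers(3, 9)), seed=trial)
            edges = [(f"v{a}", f"v{b}") for a, b in G.edges]
            if not edges:
                continue
            values = np.round(rng.random(len(edges)), 3)
            query = "v0"
            module = extract_module(masks_from(edges, values, query=query))
            best, best_total = None, -1.0
            for r in range(len(edges) + 1):
                for subset in itertools.combinations(range(len(edges)), r):
                    sub = [edges[i] for i in subset]
                    H = nx.Graph(sub)
                    H.add_node(query)
                    if not nx.is_connected(H.subgraph(
                        nx.node_connected_component(H, query))):
                        continue
                    if set(H.nodes) - nx.node_connected_component(H, query):
                        continue
                    total = values[list(subset)].sum()
                    if total > best_total:
                        best, best_total = set(sub), total
            assert set(module.edges) == {tuple(sorted(e)) for e in best} or \
                set(map(tuple, map(sorted, module.edges))) == \
                {tuple(sorted(e)) for e in best}

    def test_equal_masks_tie_break_reproducible_and_lexicographic(self):
        edges = [("q", "b"), ("q", "a"), ("a", "c"), ("b", "d")]
        m = masks_from(edges, [0.5] * 4)
        m1 = extract_module(m, max_edges=2)
        m2 = extract_module(m, max_edges=2)
        assert m1.edges == m2.edges
        # first pick: lexicographically smallest frontier pair (a, q) vs (b, q)
        assert m1.edges[0] == ("q", "a")

    def test_isolated_query_gives_singleton(self):
        m = masks_from([], np.array([]), query="q", nodes=["q"])
        module = extract_module(m)
        assert module.genes == ["q"] and module.edges == []

    def test_disconnected_high_mask_edge_not_taken(self):
        edges = [("q", "a"), ("x", "y")]
        module = extract_module(masks_from(edges, [0.2, 0.99]))
        assert module.edges == [("q", "a")]


class TestRepresentativeFeatures:
    def test_tenfold_boundary_inclusive(self):
        assert representative_features([10.0, 1.0, 1.0, 1.0]) == [0]

    def test_all_equal_gives_empty(self):
        assert representative_features([2.0, 2.0, 2.0]) == []

    def test_just_below_boundary_excluded(self):
        assert representative_features([9.99, 1.0, 1.0]) == []

    def test_all_zero_warns_empty(self):
        with pytest.warns(UserWarning, match="zero"):
            assert representative_features([0.0, 0.0]) == []

    def test_min_taken_over_positive_scores(self):
        # a zero entry must not make every feature representative
        assert representative_features([0.0, 1.0, 5.0, 10.0]) == [3]

    def test_grouped_to_named_blocks(self):
        widths = {"ATAC": 1, "SNV": 1, "HiC": 2}
        scores = [0.01, 0.5, 0.02, 0.01]
        assert rf_blocks(scores, widths) == ["SNV"]


class TestStability:
    def test_identical_seeds_full_jaccard(self, trained_snv_model, snv_only_graph):
        g = snv_only_graph
        q = g.gene_ids[int(np.argmax(trained_snv_model.decision_function()))]
        score = stability_check(
            trained_snv_model.net_, g, q, seed_list=[3, 3], epochs=15
        )
        assert score == 1.0

    def test_disjoint_modules_zero(self, rng, monkeypatch):
        from oncomod import explain as ex_mod
        from oncomod.explain import GeneModule

        g = random_multiomics_graph(rng, n_nodes=6)
        fake = iter([
            GeneModule("q", ["a", "b"], [], np.array([1.0, 1.0])),
            GeneModule("q", ["c", "d"], [], np.array([1.0, 1.0])),
        ])
        monkeypatch.setattr(
            ex_mod.GNNMaskExplainer, "explain",
            lambda self, *a, **k: next(fake),
        )
        assert stability_check(None, g, "q", seed_list=[0, 1]) == 0.0

    def test_dominant_signal_is_consistent(self, trained_snv_model, snv_only_graph):
        g = snv_only_graph
        q = g.gene_ids[int(np.argmax(trained_snv_model.decision_function()))]
        score = stability_check(
            trained_snv_model.net_, g, q, seed_list=[0, 1, 2], epochs=60
        )
        assert score >= 0.8


def test_emitted_modules_satisfy_hard_constraints(
    trained_snv_model, snv_only_graph
):
    """Connected, query included, <= 20 edges, all genes within 2 hops."""
    g = snv_only_graph
    G_full = g.to_networkx()
    scores = trained_snv_model.decision_function()
    queries = [g.gene_ids[i] for i in np.argsort(-scores)[:4]]
    ex = GNNMaskExplainer(trained_snv_model.net_, epochs=40)
    for q in queries:
        module = ex.explain(g, q, seed=0)
        assert q in module.genes
        assert len(module.edges) <= 20
        H = nx.Graph(module.edges)
        H.add_nodes_from(module.genes)
        assert nx.is_connected(H)
        dist = nx.single_source_shortest_path_length(G_full, q, cutoff=2)
        assert all(gene in dist for gene in module.genes)
        assert ((module.feature_importance >= 0)
                & (module.feature_importance <= 1)).all()


def test_module_json_round_trip():
    from oncomod.explain import GeneModule

    m = GeneModule("q", ["a", "q"], [("a", "q")], np.array([0.1, 0.9]), [1], "seed0")
    back = GeneModule.from_json(m.to_json())
    assert back.query_gene == "q" and back.edges == [("a", "q")]
    np.testing.assert_allclose(back.feature_importance, m.feature_importance)
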