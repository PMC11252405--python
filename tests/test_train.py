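"""Warm-up schedule, metrics, early stopping, CV ensembling, transfer."""

import itertools

import numpy as np
import pandas as pd
import pytest

from oncomod.graph import make_splits
from oncomod.pipeline import build_graph
from oncomod.synthetic import SyntheticConfig, generate
from oncomod.train import (
    GraphTransformerClassifier,
    TrainConfig,
    downsample_negatives,
    ensemble_predict,
    evaluate,
    fine_tune,
    train_cv,
    warmup_lr,
)


class TestWarmupLr:
    cfg = TrainConfig()

    @pytest.mark.parametrize("step,expected", [
        (0, 0.0),
        (100, 0.0025),   # 10% of 1000 steps: halfway up the ramp
        (200, 0.005),    # end of the 20% warm-up: peak
        (999, 0.005),    # stays at peak afterwards
    ])
    def test_schedule_values(self, step, expected):
        assert warmup_lr(step, 1000, self.cfg) == pytest.approx(expected)

    def test_zero_total_steps_errors(self):
        with pytest.raises(ValueError):
            warmup_lr(0, 0, self.cfg)

    def test_monotone_nondecreasing(self):
        lrs = [warmup_lr(s, 500, self.cfg) for s in range(501)]
        assert all(b >= a for a, b in zip(lrs, lrs[1:]))


# ---------------------------------------------------------------------------
# metrics vs an exhaustive-threshold oracle
# ---------------------------------------------------------------------------

def auroc_oracle(scores, labels):
    """Concordant-pair count; ties count one half (Mann-Whitney)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def auprc_oracle(scores, labels):
    """Step-interpolated average precision: sum (R_k - R_{k-1}) * P_k."""
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    tp = fp = 0
    n_pos = labels.sum()
    out, prev_recall = 0.0, 0.0
    for i, y in enumerate(labels):
        tp += y
        fp += 1 - y
        # step only at distinct-threshold boundaries
        if i + 1 < len(labels) and scores[order][i + 1] == scores[order][i]:
            continue
        recall = tp / n_pos
        precision = tp / (tp + fp)
        out += (recall - prev_recall) * precision
        prev_recall = recall
    return out


def test_evaluate_worked_example(toy):
    scores, labels = toy["scores4"]
    rep = evaluate(scores, labels)
    assert rep.auroc == pytest.approx(0.75)
    assert rep.auprc == pytest.approx(0.8333, abs=1e-4)
    assert rep.accuracy == pytest.approx(0.5)


def test_perfect_separation_scores_one():
    rep = evaluate(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
    assert rep.auprc == rep.auroc == rep.accuracy == rep.f1 == 1.0


def test_evaluate_matches_oracle_on_all_label_patterns(rng):
    """All 2^6 label patterns (with both classes) x random score vectors."""
    for bits in itertools.product([0, 1], repeat=6):
        labels = np.array(bits)
        if labels.min() == labels.max():
            with pytest.raises(ValueError):
                evaluate(rng.random(6), labels)
            continue
        scores = np.round(rng.random(6), 1)  # coarse grid to exercise ties
        rep = evaluate(scores, labels)
        assert rep.auroc == pytest.approx(auroc_oracle(scores, labels), abs=1e-12)
        assert rep.auprc == pytest.approx(auprc_oracle(scores, labels), abs=1e-9)
        pred = scores >= 0.5
        assert rep.accuracy == pytest.approx((pred == labels).mean())


# ---------------------------------------------------------------------------
# training loop behavior
# ---------------------------------------------------------------------------

def tiny_graph(rng, n=30, n_feat=4):
    from tests.conftest import random_multiomics_graph

    g = random_multiomics_graph(rng, n_nodes=n, n_features=n_feat, edge_prob=0.2)
    y = np.full(n, -1)
    y[: n // 2] = rng.integers(0, 2, size=n // 2)
    y[:2] = [1, 0]  # guarantee both classes
    g.y = y
    return g


def test_early_stop_counter_hand_trace(rng):
    """patience=1 with a frozen (zero) learning rate stops after 2 epochs."""
    g = tiny_graph(rng)
    labeled = np.flatnonzero(g.y >= 0)
    clf = GraphTransformerClassifier(
        peak_lr=0.0, patience=1, max_epochs=50, random_state=0
    )
    clf.fit(g.X, g.y, edge_index=g.edge_index(),
            train_idx=labeled[:10], val_idx=labeled[10:])
    assert len(clf.history_) == 2


def test_best_epoch_weights_restored(trained_snv_model):
    hist = trained_snv_model.history_
    best = trained_snv_model.best_epoch_
    vals = [h["val_auprc"] for h in hist]
    assert vals[best] == max(vals)
    assert all(vals[best] >= v for v in vals[best + 1:])


def test_fit_is_deterministic_per_seed(rng):
    g = tiny_graph(rng)
    labeled = np.flatnonzero(g.y >= 0)
    kw = dict(edge_index=g.edge_index(), train_idx=labeled[:10], val_idx=labeled[10:])
    a = GraphTransformerClassifier(max_epochs=10, random_state=7).fit(g.X, g.y, **kw)
    b = GraphTransformerClassifier(max_epochs=10, random_state=7).fit(g.X, g.y, **kw)
    for wa, wb in zip(a.net_.get_weights(), b.net_.get_weights()):
        np.testing.assert_array_equal(wa, wb)


class TestDownsampleNegatives:
    def test_removes_floor_half(self):
        genes = [f"g{i}" for i in range(25)]
        labels = {g: (1 if i < 5 else 0) for i, g in enumerate(genes)}
        kept, removed = downsample_negatives(genes, labels, 0.5, seed=0)
        assert len(removed) == 10  # floor(0.5 * 20)
        assert all(labels[g] == 0 for g in removed)
        assert set(kept) | set(removed) == set(genes)

    def test_seeded_and_positive_preserving(self):
        genes = [f"g{i}" for i in range(40)]
        labels = {g: (1 if i % 4 == 0 else 0) for i, g in enumerate(genes)}
        k1, r1 = downsample_negatives(genes, labels, 0.5, seed=3)
        k2, r2 = downsample_negatives(genes, labels, 0.5, seed=3)
        assert k1 == k2 and r1 == r2
        assert all(labels[g] == 1 for g in set(genes) - set(k1) - set(r1) | set())


class FixedScoreModel:
    """Stand-in classifier producing a constant score (for ensemble math)."""

    def __init__(self, score, n_features=2):
        self.score = score
        self.n_features_in_ = n_features

    def decision_function(self, X, edge_index=None):
        return np.full(len(X), self.score)


class TestEnsemblePredict:
    def graph(self, rng):
        return tiny_graph(rng, n=10, n_feat=2)

    def test_mean_of_model_scores(self, rng):
        g = self.graph(rng)
        models = [FixedScoreModel(s) for s in (0.2, 0.4, 0.6)]
        out = ensemble_predict(models, g)
        assert np.allclose(out["score"], 0.4)

    def test_single_model_identity_and_idempotence(self, rng):
        g = self.graph(rng)
        one = ensemble_predict([FixedScoreModel(0.3)], g)
        ten = ensemble_predict([FixedScoreModel(0.3)] * 10, g)
        assert np.allclose(one["score"], 0.3)
        assert np.allclose(ten["score"], one["score"])

    def test_empty_and_mismatched_models_error(self, rng):
        g = self.graph(rng)
        with pytest.raises(ValueError):
            ensemble_predict([], g)
        with pytest.raises(ValueError, match="width"):
            ensemble_predict(
                [FixedScoreModel(0.2, 2), FixedScoreModel(0.2, 3)], g
            )


def test_train_cv_returns_ten_models_and_fold_logs(snv_only_graph):
    g = snv_only_graph
    labels = pd.Series(g.y, index=g.gene_ids)
    splits = make_splits(labels, seed=0)
    tcfg = TrainConfig(max_epochs=6, patience=6, seed=0)
    models, logs = train_cv(g, splits, train_cfg=tcfg)
    assert len(models) == len(splits.folds) == 10
    removed = logs[0]["removed_negatives"]
    n_train_neg = sum(labels[x] == 0 for x in splits.train_genes)
    assert len(removed) == n_train_neg // 2
    assert all(log["removed_negatives"] == removed for log in logs)
    # removed negatives never overlap validation or test genes
    assert not set(removed) & set(splits.test_genes)
    for log, fold in zip(logs, splits.folds):
        assert log["n_val"] == len(fold)


class TestFineTune:
    def test_width_mismatch_names_both(self, trained_snv_model, rng):
        X8 = rng.normal(size=(10, 8))
        with pytest.raises(ValueError, match="15.*8"):
            fine_tune(trained_snv_model, X8, np.zeros(10), np.zeros((2, 0), int))

    def test_zero_epochs_is_identity(self, trained_snv_model, snv_only_graph):
        g = snv_only_graph
        tuned = fine_tune(
            trained_snv_model, g.X, g.y, g.edge_index(),
            train_cfg=TrainConfig(max_epochs=0),
        )
        np.testing.assert_array_equal(
            tuned.decision_function(), trained_snv_model.decision_function()
        )

    def test_transfer_beats_scratch_at_small_label_budget(self, trained_snv_model):
        """Pretraining on a large related task helps when labels are scarce."""
        ft_scores, scratch_scores = [], []
        for seed in range(5):
            cfg = SyntheticConfig(
                n_genes=500, n_positive=50, n_negative=150, seed=100 + seed,
                snv_effect=3.0, track_effect=0.0, hic_block_strength=0.0,
                edge_enrichment=1.0,
            )
            g = build_graph(generate(cfg))
            labeled = np.flatnonzero(g.y >= 0)
            rng = np.random.default_rng(seed)
            chosen = rng.permutation(labeled)
            budget, rest = chosen[:50], chosen[50:]
            if len(np.unique(g.y[budget])) < 2 or len(np.unique(g.y[rest])) < 2:
                continue
            tcfg = TrainConfig(max_epochs=60, patience=60, seed=seed)
            tuned = fine_tune(
                trained_snv_model, g.X, g.y, g.edge_index(), train_idx=budget,
                train_cfg=tcfg,
            )
            scratch = GraphTransformerClassifier(
                max_epochs=60, patience=60, random_state=seed
            ).fit(g.X, g.y, edge_index=g.edge_index(), train_idx=budget)
            ft_scores.append(
                evaluate(tuned.decision_function()[rest], g.y[rest]).auprc
            )
            scratch_scores.append(
                evaluate(scratch.decision_function()[rest], g.y[rest]).auprc
            )
        assert len(ft_scores) >= 4
        assert np.mean(ft_scores) >= np.mean(scratch_scores)
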