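"""Training: warm-up schedule, early stopping, CV ensembling, metrics, transfer.

The estimator follows the scikit-learn semi-supervised convention (as in
``LabelPropagation``): ``y`` holds 1 for known cancer genes, 0 for confident
non-cancer genes and -1 for unknown genes.  Unknown genes participate in
message passing but never in the loss.  Training is full-batch: with exactly
two message-passing layers, computing a node's output on its exact 1st+2nd
order neighbor subgraph and computing it on the full graph are the same
function, so one forward pass per epoch covers every training node.

The learning rate rises linearly from 0 to ``peak_lr`` over the first
``warmup_fraction`` of the total optimizer steps and stays at the peak
afterwards.  Early stopping monitors validation AUPRC with a patience
counter; the best-epoch weights are restored.  Before training, a seeded
fraction of the negative class is removed from the training pool (default:
half) to counter the label imbalance; validation and test genes are never
touched.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    roc_auc_score,
)

from ._autodiff import Adam, Tensor
from .graph import MultiOmicsGraph, SplitPlan
from .net import GraphTransformerNet, ModelConfig

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "GraphTransformerClassifier",
    "warmup_lr",
    "downsample_negatives",
    "train_cv",
    "ensemble_predict",
    "evaluate",
    "fine_tune",
]


@dataclass
class TrainConfig:
    peak_lr: float = 0.005
    warmup_fraction: float = 0.2
    patience: int = 100
    neg_keep_fraction: float = 0.5
    max_epochs: int = 300
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.warmup_fraction < 1:
            raise ValueError("warmup_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class MetricsReport:
    auprc: float
    auroc: float
    accuracy: float
    f1: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def warmup_lr(step: int, total_steps: int, cfg: TrainConfig) -> float:
    """Linear 0 -> peak over the first warmup fraction, then constant peak."""
    if total_steps <= 0:
        raise ValueError("total_steps must be > 0")
    warm = cfg.warmup_fraction * total_steps
    if step < warm:
        return cfg.peak_lr * step / warm
    return cfg.peak_lr


def _bce_from_logits(z: Tensor, y: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy from logits."""
    # log(1 + e^z) = relu(z) + log(1 + e^{-|z|});  |z| = relu(z) + relu(-z)
    absz = z.relu() + (-z).relu()
    log1pexp = z.relu() + (1.0 + (-absz).exp()).log()
    return (log1pexp - z * y).mean()


class GraphTransformerClassifier(BaseEstimator, ClassifierMixin):
    """Semi-supervised graph-transformer cancer-gene classifier.

    Parameters mirror :class:`oncomod.net.ModelConfig` and
    :class:`TrainConfig`.  ``fit(X, y, edge_index=...)`` takes the node
    feature matrix, tri-state labels (1/0/-1) and the directed edge index of
    the gene graph; the model is transductive, so ``predict_proba()`` with no
    arguments scores the training graph.
    """

    def __init__(
        self,
        hidden: int = 64,
        heads: int = 4,
        pool_stride: int = 2,
        mlp_hidden: int = 32,
        dropout_attn: float = 0.1,
        dropout: float = 0.4,
        peak_lr: float = 0.005,
        warmup_fraction: float = 0.2,
        patience: int = 100,
        max_epochs: int = 300,
        random_state: int = 0,
    ):
        self.hidden = hidden
        self.heads = heads
        self.pool_stride = pool_stride
        self.mlp_hidden = mlp_hidden
        self.dropout_attn = dropout_attn
        self.dropout = dropout
        self.peak_lr = peak_lr
        self.warmup_fraction = warmup_fraction
        self.patience = patience
        self.max_epochs = max_epochs
        self.random_state = random_state

    # -- fitting --------------------------------------------------------------
    def fit(
        self,
        X,
        y,
        edge_index: np.ndarray | None = None,
        train_idx: np.ndarray | None = None,
        val_idx: np.ndarray | None = None,
        init_weights: list[np.ndarray] | None = None,
    ) -> "GraphTransformerClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if edge_index is None:
            edge_index = np.zeros((2, 0), dtype=np.intp)
        if train_idx is None:
            train_idx = np.flatnonzero(y >= 0)
        train_idx = np.asarray(train_idx, dtype=np.intp)
        if len(train_idx) == 0:
            raise ValueError("no labeled training nodes")

        cfg = ModelConfig(
            in_dim=X.shape[1], hidden=self.hidden, heads=self.heads,
            pool_stride=self.pool_stride, mlp_hidden=self.mlp_hidden,
            dropout_attn=self.dropout_attn, dropout=self.dropout,
        )
        net = GraphTransformerNet(cfg, seed=self.random_state)
        if init_weights is not None:
            net.set_weights(init_weights)
        tcfg = TrainConfig(
            peak_lr=self.peak_lr, warmup_fraction=self.warmup_fraction,
            patience=self.patience, max_epochs=self.max_epochs,
            seed=self.random_state,
        )
        rng = np.random.default_rng(self.random_state)
        optimizer = Adam(net.params, lr=0.0)
        y_train = y[train_idx].astype(np.float64)

        best_weights = net.get_weights()
        best_val = -np.inf
        best_epoch = -1
        bad_epochs = 0
        history: list[dict] = []
        for epoch in range(self.max_epochs):
            lr = warmup_lr(epoch, self.max_epochs, tcfg)
            optimizer.lr = lr
            logits = net.logits(X, edge_index, training=True, rng=rng)
            loss = _bce_from_logits(logits[train_idx], y_train)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            record = {"epoch": epoch, "lr": lr, "train_loss": loss.item()}
            if val_idx is not None and len(val_idx):
                probs = net.predict_proba(X, edge_index)
                val_auprc = average_precision_score(y[val_idx], probs[val_idx])
                record["val_auprc"] = float(val_auprc)
                if val_auprc > best_val:
                    best_val = val_auprc
                    best_weights = net.get_weights()
                    best_epoch = epoch
                    bad_epochs = 0
                else:
                    bad_epochs += 1
                history.append(record)
                if bad_epochs >= self.patience:
                    break
            else:
                history.append(record)
        if val_idx is not None and len(val_idx) and best_epoch >= 0:
            net.set_weights(best_weights)
        self.net_ = net
        self.history_ = history
        self.best_epoch_ = best_epoch if best_epoch >= 0 else len(history) - 1
        self.classes_ = np.array([0, 1])
        self.X_ = X
        self.edge_index_ = edge_index
        self.n_features_in_ = X.shape[1]
        return self

    # -- prediction -----------------------------------------------------------
    def _scores(self, X=None, edge_index=None) -> np.ndarray:
        if X is None:
            X, edge_index = self.X_, self.edge_index_
        elif edge_index is None:
            edge_index = self.edge_index_
        return self.net_.predict_proba(np.asarray(X, dtype=np.float64), edge_index)

    def predict_proba(self, X=None, edge_index=None) -> np.ndarray:
        p = self._scores(X, edge_index)
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X=None, edge_index=None) -> np.ndarray:
        return self._scores(X, edge_index)

    def predict(self, X=None, edge_index=None) -> np.ndarray:
        return (self._scores(X, edge_index) >= 0.5).astype(np.int64)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def downsample_negatives(
    train_genes: list[str], labels: dict[str, int], keep_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Remove ``floor((1 - keep_fraction) * n_neg)`` training negatives, seeded.

    Returns (kept training genes, removed negatives).  Validation/test genes
    are the caller's responsibility and never pass through here.
    """
    negatives = sorted(g for g in train_genes if labels[g] == 0)
    n_remove = int(np.floor((1.0 - keep_fraction) * len(negatives)))
    rng = np.random.default_rng(seed)
    removed = set(rng.choice(negatives, size=n_remove, replace=False)) if n_remove else set()
    kept = [g for g in train_genes if g not in removed]
    return kept, sorted(removed)


def train_cv(
    graph: MultiOmicsGraph,
    splits: SplitPlan,
    model_cfg: dict | None = None,
    train_cfg: TrainConfig | None = None,
) -> tuple[list[GraphTransformerClassifier], list[dict]]:
    """Train one model per CV fold; returns the models and per-fold logs.

    Negative downsampling is drawn once per run (seeded with the run seed)
    over the whole training pool and applied to every fold's training split.
    Each fold's own genes serve as its validation set for early stopping.
    """
    train_cfg = train_cfg or TrainConfig()
    model_cfg = model_cfg or {}
    labels = {g: int(graph.y[graph.index_of(g)]) for g in graph.gene_ids}
    all_train = splits.train_genes
    kept_train, removed = downsample_negatives(
        all_train, labels, train_cfg.neg_keep_fraction, train_cfg.seed
    )
    edge_index = graph.edge_index()
    X = graph.X
    models, logs = [], []
    for fold_i, val_genes in enumerate(splits.folds):
        val_set = set(val_genes)
        if len({labels[g] for g in val_genes}) < 2:
            raise ValueError(f"fold {fold_i} is missing a class")
        fold_train = [g for g in kept_train if g not in val_set]
        if len({labels[g] for g in fold_train}) < 2:
            raise ValueError(f"fold {fold_i} training set is missing a class")
        train_idx = np.array([graph.index_of(g) for g in fold_train], dtype=np.intp)
        val_idx = np.array([graph.index_of(g) for g in val_genes], dtype=np.intp)
        clf = GraphTransformerClassifier(
            peak_lr=train_cfg.peak_lr,
            warmup_fraction=train_cfg.warmup_fraction,
            patience=train_cfg.patience,
            max_epochs=train_cfg.max_epochs,
            random_state=train_cfg.seed * 100 + fold_i,
            **model_cfg,
        )
        clf.fit(X, graph.y, edge_index=edge_index, train_idx=train_idx, val_idx=val_idx)
        models.append(clf)
        logs.append({
            "fold": fold_i,
            "best_epoch": clf.best_epoch_,
            "n_train": len(fold_train),
            "n_val": len(val_genes),
            "removed_negatives": removed,
            "history": clf.history_,
        })
    return models, logs


def ensemble_predict(
    models: list[GraphTransformerClassifier],
    graph: MultiOmicsGraph,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Arithmetic mean of per-model probabilities for the requested genes."""
    if not models:
        raise ValueError("need at least one model")
    in_dims = {m.n_features_in_ for m in models}
    if len(in_dims) > 1:
        raise ValueError(f"models disagree on feature width: {sorted(in_dims)}")
    edge_index = graph.edge_index()
    scores = np.mean(
        [m.decision_function(graph.X, edge_index) for m in models], axis=0
    )
    genes = genes if genes is not None else graph.gene_ids
    idx = [graph.index_of(g) for g in genes]
    return pd.DataFrame({
        "gene_id": genes,
        "score": scores[idx],
        "label": graph.y[idx],
        "model_index": "ensemble",
    })


def evaluate(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """AUPRC (step-interpolated average precision), AUROC (Mann-Whitney,
    ties count 1/2), accuracy and F1 at the given probability threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes to evaluate")
    pred = (scores >= threshold).astype(np.int64)
    return MetricsReport(
        auprc=float(average_precision_score(labels, scores)),
        auroc=float(roc_auc_score(labels, scores)),
        accuracy=float(accuracy_score(labels, pred)),
        f1=float(f1_score(labels, pred)),
    )


def fine_tune(
    pretrained: GraphTransformerClassifier,
    X: np.ndarray,
    y: np.ndarray,
    edge_index: np.ndarray,
    train_idx: np.ndarray | None = None,
    val_idx: np.ndarray | None = None,
    train_cfg: TrainConfig | None = None,
) -> GraphTransformerClassifier:
    """Continue training a pretrained model on a new labeled graph.

    The new graph must have the same feature width; with ``max_epochs=0``
    the returned model's predictions equal the pretrained model's.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != pretrained.n_features_in_:
        raise ValueError(
            f"feature width mismatch: pretrained expects "
            f"{pretrained.n_features_in_}, new graph has {X.shape[1]}"
        )
    train_cfg = train_cfg or TrainConfig()
    clf = GraphTransformerClassifier(**pretrained.get_params())
    clf.set_params(
        peak_lr=train_cfg.peak_lr, warmup_fraction=train_cfg.warmup_fraction,
        patience=train_cfg.patience, max_epochs=train_cfg.max_epochs,
        random_state=train_cfg.seed,
    )
    if train_cfg.max_epochs == 0:
        clf = copy.deepcopy(pretrained)
        clf.X_, clf.edge_index_ = X, edge_index
        return clf
    clf.fit(
        X, y, edge_index=edge_index, train_idx=train_idx, val_idx=val_idx,
        init_weights=pretrained.net_.get_weights(),
    )
    return clf
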