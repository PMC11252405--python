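"""Graph-transformer node classifier.

Architecture (forward pass, for node *i* with input feature vector x_i):

1. graph-transformer layer:  ``x'_i = W1 x_i + sum_{j in N(i)} a_ij W2 x_j``
   with per-head attention ``a_ij = softmax_j((W3 x_i)^T (W4 x_j) / sqrt(d))``
   over the neighbors N(i) (self excluded; the self term is W1), multi-head
   outputs concatenated to width ``heads * d``;
2. layer norm (per-node mean/variance, learnable affine);
3. second graph-transformer layer on the residual input concatenation
   ``[h_i, x_i]`` — the raw features ride along to fight over-smoothing;
4. layer norm;
5. 1-D max-pooling over consecutive channel pairs (stride 2: 64 -> 32);
6. linear -> 32, ReLU, dropout, linear -> 1, sigmoid.

Dropout: 0.1 on the attention weights, 0.4 elsewhere (training only).
All tensors run on the package's numpy autodiff (:mod:`oncomod._autodiff`);
the explainer reuses this exact forward pass with multiplicative edge and
feature masks, so mask = 1 reproduces predictions bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ._autodiff import Tensor, concat, gather_rows, scatter_sum, segment_max

__all__ = [
    "ModelConfig",
    "LayerNorm",
    "GraphTransformerConv",
    "GraphTransformerNet",
    "layer_norm",
    "attention_coefficients",
    "graph_transformer_layer",
]

CHECKPOINT_SCHEMA = 1


@dataclass
class ModelConfig:
    in_dim: int
    hidden: int = 64
    heads: int = 4
    pool_stride: int = 2
    mlp_hidden: int = 32
    dropout_attn: float = 0.1
    dropout: float = 0.4
    eps: float = 1e-5

    def __post_init__(self):
        if self.hidden % self.heads:
            raise ValueError("hidden must be divisible by heads")
        if self.hidden % self.pool_stride:
            raise ValueError("hidden must be divisible by pool_stride")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class LayerNorm:
    """Per-vector normalization with learnable affine (gamma, beta)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)  # population variance
        return (x - mu) / (var + self.eps).sqrt() * self.gamma + self.beta

    @property
    def params(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class GraphTransformerConv:
    """One multi-head graph-transformer convolution (W1..W4)."""

    def __init__(self, in_dim: int, heads: int, d: int, rng: np.random.Generator):
        self.heads, self.d = heads, d
        out = heads * d
        self.W1 = Tensor(_glorot(rng, in_dim, out), requires_grad=True)
        self.W2 = Tensor(_glorot(rng, in_dim, out), requires_grad=True)
        self.W3 = Tensor(_glorot(rng, in_dim, out), requires_grad=True)
        self.W4 = Tensor(_glorot(rng, in_dim, out), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [self.W1, self.W2, self.W3, self.W4]

    def __call__(
        self,
        X: Tensor,
        edge_index: np.ndarray,
        edge_weight: Tensor | None = None,
        attn_dropout_mask: np.ndarray | None = None,
    ) -> Tensor:
        n = X.shape[0]
        skip = X @ self.W1
        if edge_index.shape[1] == 0:
            return skip
        src, dst = edge_index
        heads, d = self.heads, self.d
        Q = (X @ self.W3).reshape(n, heads, d)
        K = (X @ self.W4).reshape(n, heads, d)
        V = (X @ self.W2).reshape(n, heads, d)
        scores = (gather_rows(Q, dst) * gather_rows(K, src)).sum(axis=2) / np.sqrt(d)
        # numerically stable softmax over each destination's neighbor set
        shift = segment_max(scores.data, dst, n)
        e = (scores - shift[dst]).exp()
        denom = gather_rows(scatter_sum(e, dst, n), dst)
        alpha = e / denom  # (E, heads), sums to 1 per (dst, head)
        if edge_weight is not None:
            alpha = alpha * edge_weight.reshape(-1, 1)
        if attn_dropout_mask is not None:
            alpha = alpha * attn_dropout_mask
        msg = alpha.reshape(-1, heads, 1) * gather_rows(V, src)
        agg = scatter_sum(msg, dst, n).reshape(n, heads * d)
        return skip + agg


class GraphTransformerNet:
    """The full classifier network (parameters + forward pass)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        d = c.hidden // c.heads
        self.conv1 = GraphTransformerConv(c.in_dim, c.heads, d, rng)
        self.ln1 = LayerNorm(c.hidden, c.eps)
        self.conv2 = GraphTransformerConv(c.hidden + c.in_dim, c.heads, d, rng)
        self.ln2 = LayerNorm(c.hidden, c.eps)
        pooled = c.hidden // c.pool_stride
        self.Wl1 = Tensor(_glorot(rng, pooled, c.mlp_hidden), requires_grad=True)
        self.bl1 = Tensor(np.zeros(c.mlp_hidden), requires_grad=True)
        self.Wl2 = Tensor(_glorot(rng, c.mlp_hidden, 1), requires_grad=True)
        self.bl2 = Tensor(np.zeros(1), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return (
            self.conv1.params + self.ln1.params + self.conv2.params + self.ln2.params
            + [self.Wl1, self.bl1, self.Wl2, self.bl2]
        )

    def _check_finite(self):
        for p in self.params:
            if not np.isfinite(p.data).all():
                raise ValueError("NaN or Inf in model parameters")

    def logits(
        self,
        X,
        edge_index: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        edge_mask: Tensor | None = None,
        feature_mask: Tensor | None = None,
    ) -> Tensor:
        """Pre-sigmoid output per node, shape (n,)."""
        self._check_finite()
        c = self.config
        X = X if isinstance(X, Tensor) else Tensor(X)
        if X.shape[1] != c.in_dim:
            raise ValueError(f"expected {c.in_dim} features, got {X.shape[1]}")
        if feature_mask is not None:
            X = X * feature_mask
        drop_attn = drop1 = drop2 = None
        if training:
            if rng is None:
                rng = np.random.default_rng()
            e = edge_index.shape[1]
            keep_a, keep_o = 1.0 - c.dropout_attn, 1.0 - c.dropout
            drop_attn = rng.binomial(1, keep_a, size=(e, c.heads)) / keep_a
            drop1 = rng.binomial(1, keep_o, size=(X.shape[0], c.hidden)) / keep_o
            drop2 = rng.binomial(1, keep_o, size=(X.shape[0], c.mlp_hidden)) / keep_o
        h = self.conv1(X, edge_index, edge_mask, drop_attn)
        h = self.ln1(h)
        if drop1 is not None:
            h = h * drop1
        h = self.conv2(concat([h, X], axis=1), edge_index, edge_mask, drop_attn)
        h = self.ln2(h)
        pooled = h.reshape(-1, c.hidden // c.pool_stride, c.pool_stride).max(axis=2)
        z = (pooled @ self.Wl1 + self.bl1).relu()
        if drop2 is not None:
            z = z * drop2
        return (z @ self.Wl2 + self.bl2).reshape(-1)

    def forward(self, X, edge_index, **kwargs) -> Tensor:
        """Per-node probability of being a cancer gene, in (0, 1)."""
        return self.logits(X, edge_index, **kwargs).sigmoid()

    def predict_proba(self, X, edge_index: np.ndarray) -> np.ndarray:
        return self.forward(X, edge_index).data

    # -- weight plumbing ------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            if p.data.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.data.shape} vs {w.shape}")
            p.data = np.array(w, dtype=np.float64)

    def save(self, path: str) -> None:
        arrays = {f"w{i}": w for i, w in enumerate(self.get_weights())}
        meta = {"schema": CHECKPOINT_SCHEMA, "config": asdict(self.config)}
        np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str) -> "GraphTransformerNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            if meta["schema"] != CHECKPOINT_SCHEMA:
                raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
            net = cls(ModelConfig(**meta["config"]))
            net.set_weights([data[f"w{i}"] for i in range(len(net.params))])
        return net


# ---------------------------------------------------------------------------
# functional forms (thin wrappers used in tests and docs)
# ---------------------------------------------------------------------------

def layer_norm(x: np.ndarray, gamma=1.0, beta=0.0, eps: float = 1e-5) -> np.ndarray:
    """Normalize a vector to zero mean / unit variance, then affine-shift."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("layer_norm needs a nonempty vector")
    return (x - x.mean()) / np.sqrt(x.var() + eps) * gamma + beta


def attention_coefficients(
    xi: np.ndarray, xj_list: np.ndarray, W3: np.ndarray, W4: np.ndarray,
    d: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw scaled-dot-product scores and their softmax over the neighbors."""
    xj_list = np.atleast_2d(xj_list)
    if xj_list.shape[0] == 0:
        raise ValueError("neighbor list must be nonempty")
    if d is None:
        d = W3.shape[1]
    q = W3.T @ np.asarray(xi, dtype=np.float64)
    raw = (xj_list @ W4.T) @ q / np.sqrt(d)
    e = np.exp(raw - raw.max())
    return raw, e / e.sum()


def graph_transformer_layer(
    X: np.ndarray, edge_index: np.ndarray, conv: GraphTransformerConv
) -> np.ndarray:
    """Single convolution applied functionally (no dropout, no masks)."""
    return conv(Tensor(X), edge_index).data
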