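"""Graph-transformer encoder with triangular multiplicative edge updates.

Node embeddings are updated by multi-head attention in which keys are
shifted by a learned projection of the incident edge feature, attention
weights are the normalized exponentials of the scaled dot products, and
per-head messages sum value and edge projections.  A gated residual mixes
the attended update with the previous embedding, followed by a
feed-forward transition.  Edge embeddings are updated by the
outgoing-then-incoming triangular multiplicative operation: gated linear
maps form "left" and "right" edge transforms a_ij and b_ij, and each edge
ij accumulates the elementwise product over the third triangle vertex k.

Four such blocks (node update, outgoing edge update, incoming edge update)
form the encoder.  Layer normalization is applied pre-sublayer.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concat, einsum, softmax
from .config import ModelConfig
from .nn import LayerNorm, Linear, Module

__all__ = ["GTLayer", "TriangleUpdate", "Encoder"]


def _softmax_lastaxis_over(logits: Tensor, axis: int) -> Tensor:
    """Stable softmax along `axis` (max-shifted exponentials)."""
    return softmax(logits, axis=axis)


class GTLayer(Module):
    """One graph-transformer node update (attention + gated residual + FF)."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        d, de = config.d_node, config.d_edge
        self.n_head = config.n_gt_head
        self.d_head = config.d_gt_head
        hd = self.n_head * self.d_head
        self.norm_nodes = LayerNorm(d)
        self.norm_edges = LayerNorm(de)
        self.W_q = Linear(d, hd, rng)
        self.W_k = Linear(d, hd, rng)
        self.W_v = Linear(d, hd, rng)
        self.W_e = Linear(de, hd, rng)
        self.W_O = Linear(hd, d, rng)
        self.W_g = Linear(3 * d, 1, rng)
        self.norm_ff = LayerNorm(d)
        self.ff1 = Linear(d, config.gt_ff_dim, rng)
        self.ff2 = Linear(config.gt_ff_dim, d, rng)

    def __call__(self, nodes: Tensor, edges: Tensor) -> Tensor:
        if not (np.all(np.isfinite(nodes.numpy()))
                and np.all(np.isfinite(edges.numpy()))):
            raise ValueError("non-finite encoder inputs")
        L = nodes.shape[0]
        C, dh = self.n_head, self.d_head
        hn = self.norm_nodes(nodes)
        en = self.norm_edges(edges)
        q = self.W_q(hn).reshape(L, C, dh)
        k = self.W_k(hn).reshape(L, C, dh)
        v = self.W_v(hn).reshape(L, C, dh)
        e = self.W_e(en).reshape(L, L, C, dh)
        # attention: q_i · (k_j + e_ij) / sqrt(d), exponential-normalized
        # over j; distributing q over (k + e) avoids (L,L,C,d) intermediates
        logits = (einsum("icd,jcd->ijc", q, k)
                  + einsum("icd,ijcd->ijc", q, e)) / math.sqrt(dh)
        alpha = _softmax_lastaxis_over(logits, axis=1)
        h_hat = (einsum("ijc,jcd->icd", alpha, v)
                 + einsum("ijc,ijcd->icd", alpha, e)).reshape(L, C * dh)
        h_hat = self.W_O(h_hat)
        beta = self.W_g(concat([h_hat, nodes, h_hat - nodes], axis=-1)).sigmoid()
        h1 = (1.0 - beta) * nodes + beta * h_hat
        h2 = h1 + self.ff2(self.ff1(self.norm_ff(h1)).relu())
        return h2

    def attention_weights(self, nodes: Tensor, edges: Tensor) -> np.ndarray:
        """(L, L, heads) attention array, for diagnostics/tests."""
        L = nodes.shape[0]
        C, dh = self.n_head, self.d_head
        hn = self.norm_nodes(nodes)
        en = self.norm_edges(edges)
        q = self.W_q(hn).reshape(L, C, dh)
        k = self.W_k(hn).reshape(L, C, dh)
        e = self.W_e(en).reshape(L, L, C, dh)
        logits = (einsum("icd,jcd->ijc", q, k)
                  + einsum("icd,ijcd->ijc", q, e)) / math.sqrt(dh)
        return _softmax_lastaxis_over(logits, axis=1).numpy()


class TriangleUpdate(Module):
    """Triangular multiplicative edge update, outgoing or incoming."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator,
                 direction: str):
        if direction not in ("outgoing", "incoming"):
            raise ValueError("direction must be 'outgoing' or 'incoming'")
        de = config.d_edge
        self.direction = direction
        self.norm = LayerNorm(de)
        self.W_a_v = Linear(de, 2 * de, rng)
        self.W_a_g = Linear(de, 2 * de, rng)
        self.W_b_v = Linear(de, 2 * de, rng)
        self.W_b_g = Linear(de, 2 * de, rng)
        self.W_c_v = Linear(2 * de, de, rng)
        self.W_c_g = Linear(de, de, rng)

    def __call__(self, edges: Tensor) -> Tensor:
        en = self.norm(edges)
        a = self.W_a_g(en).sigmoid() * self.W_a_v(en)
        b = self.W_b_g(en).sigmoid() * self.W_b_v(en)
        if self.direction == "outgoing":
            summed = einsum("ikc,jkc->ijc", a, b)
        else:
            summed = einsum("kic,kjc->ijc", a, b)
        update = self.W_c_g(en).sigmoid() * self.W_c_v(summed)
        return edges + update


class Encoder(Module):
    """Stack of (node update, outgoing, incoming) blocks."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.blocks = []
        for _ in range(config.n_gt_layers):
            self.blocks.append(GTLayer(config, rng))
            self.blocks.append(TriangleUpdate(config, rng, "outgoing"))
            self.blocks.append(TriangleUpdate(config, rng, "incoming"))

    def __call__(self, nodes: Tensor, edges: Tensor) -> tuple[Tensor, Tensor]:
        for block in self.blocks:
            if isinstance(block, GTLayer):
                nodes = block(nodes, edges)
            else:
                edges = block(edges)
        return nodes, edges
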