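"""Language-model feature front end.

A pre-trained antibody language model supplies, per chain, an L×512 final
hidden state and an L×L×64 stack of attention maps (8 layers × 8 heads).
This module projects those to the node/edge feature bundle the network
consumes and assembles paired chains.  A deterministic synthetic embedder
with the same output shapes stands in for the pre-trained model so the
whole stack is testable offline; any embedder producing
:class:`LanguageModelOutput` can be plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .config import ModelConfig
from .nn import Linear, Module

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

__all__ = ["LanguageModelOutput", "EmbeddingBundle", "SyntheticEmbedder",
           "EmbeddingProjector", "pair_chains", "unpair_chains"]


@dataclass
class LanguageModelOutput:
    """Raw per-chain language-model features."""

    sequence: str
    hidden_states: np.ndarray     # (L, 512)
    attention_stack: np.ndarray   # (L, L, layers*heads), row-normalized maps

    def __post_init__(self):
        L = len(self.sequence)
        self.hidden_states = np.asarray(self.hidden_states, dtype=np.float64)
        self.attention_stack = np.asarray(self.attention_stack, dtype=np.float64)
        if self.hidden_states.shape[0] != L:
            raise ValueError("hidden_states length != sequence length")
        if self.attention_stack.shape[:2] != (L, L):
            raise ValueError("attention_stack not L x L")


@dataclass
class EmbeddingBundle:
    """Node features h_i (L×d_node) and edge features e_ij (L×L×d_edge)."""

    nodes: Tensor                # (L, d_node)
    edges: Tensor                # (L, L, d_edge)
    chain_boundary: int          # heavy-chain length (== L for single chain)

    @property
    def length(self) -> int:
        return self.nodes.shape[0]


class SyntheticEmbedder:
    """Deterministic stand-in emulating the language-model output shapes.

    Hidden states combine a per-residue one-hot code with smoothed,
    seeded positional noise (the real embedder carries positional
    information per chain, so the stand-in encodes position explicitly).
    Attention maps are strictly positive and row-normalized.
    """

    def __init__(self, config: ModelConfig | None = None, seed: int | None = None):
        self.config = config or ModelConfig()
        self.seed = self.config.embedder_seed if seed is None else seed

    def __call__(self, sequence: str) -> LanguageModelOutput:
        bad = [i for i, a in enumerate(sequence) if a not in AMINO_ACIDS]
        if bad:
            raise ValueError(f"invalid residue letter(s) at position(s) {bad}")
        L = len(sequence)
        d = self.config.lm_hidden_dim
        n_maps = self.config.lm_attn_stack_dim
        # per-residue embedding table derived only from (seed), so identical
        # letters share features; position enters through a smooth channel
        rng = np.random.default_rng(self.seed)
        table = rng.normal(0.0, 1.0, size=(len(AMINO_ACIDS), d))
        idx = np.array([AMINO_ACIDS.index(a) for a in sequence])
        hidden = table[idx].copy()
        pos = np.arange(L)[:, None] / max(L, 1)
        freqs = np.arange(1, 9)[None, :]
        pos_feat = np.concatenate([np.sin(np.pi * pos * freqs),
                                   np.cos(np.pi * pos * freqs)], axis=1)
        hidden[:, : pos_feat.shape[1]] += pos_feat
        # smoothed positional noise so neighbouring residues correlate
        noise = rng.normal(0.0, 0.3, size=(L + 4, d))
        kernel = np.array([0.1, 0.2, 0.4, 0.2, 0.1])
        smooth = np.stack([np.convolve(noise[:, j], kernel, mode="valid")
                           for j in range(d)], axis=1)
        hidden += smooth
        # attention maps: distance-decaying positive scores, row-normalized
        seq_rng = np.random.default_rng(
            (self.seed * 1_000_003 + hash_sequence(sequence)) % 2**31)
        dist = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
        maps = np.empty((L, L, n_maps))
        for m in range(n_maps):
            scale = 1.0 + 4.0 * (m / max(n_maps - 1, 1))
            logits = -dist / scale + 0.5 * seq_rng.normal(size=(L, L))
            ex = np.exp(logits - logits.max(axis=1, keepdims=True))
            maps[:, :, m] = ex / ex.sum(axis=1, keepdims=True)
        return LanguageModelOutput(sequence, hidden, maps)


def hash_sequence(sequence: str) -> int:
    """Deterministic (process-independent) sequence hash."""
    h = 0
    for ch in sequence:
        h = (h * 131 + ord(ch)) % 2_147_483_647
    return h


class EmbeddingProjector(Module):
    """Affine maps from raw language-model features to the bundle:
    hidden states → nodes (fully connected), stacked attentions → edges
    (position-wise fully connected)."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.node_proj = Linear(config.lm_hidden_dim, config.d_node, rng)
        self.edge_proj = Linear(config.lm_attn_stack_dim, config.d_edge, rng)
        self.config = config

    def __call__(self, lm_out: LanguageModelOutput) -> EmbeddingBundle:
        L = len(lm_out.sequence)
        if lm_out.hidden_states.shape != (L, self.config.lm_hidden_dim):
            raise ValueError(
                f"hidden_states axis 1 is {lm_out.hidden_states.shape[1]}, "
                f"expected {self.config.lm_hidden_dim}")
        if lm_out.attention_stack.shape != (L, L, self.config.lm_attn_stack_dim):
            raise ValueError(
                f"attention_stack last axis is {lm_out.attention_stack.shape[-1]}, "
                f"expected {self.config.lm_attn_stack_dim}")
        nodes = self.node_proj(Tensor(lm_out.hidden_states))
        edges = self.edge_proj(Tensor(lm_out.attention_stack))
        return EmbeddingBundle(nodes, edges, chain_boundary=L)


def pair_chains(heavy: EmbeddingBundle, light: EmbeddingBundle | None
                ) -> EmbeddingBundle:
    """Concatenate chain bundles; inter-chain edge blocks start at zero.

    No chain-break token is inserted — positional information is already
    per-chain in the upstream embedder.  A missing/empty light bundle
    returns the heavy bundle unchanged (nanobody path).
    """
    if light is None or light.length == 0:
        return EmbeddingBundle(heavy.nodes, heavy.edges, heavy.length)
    dn_h, dn_l = heavy.nodes.shape[-1], light.nodes.shape[-1]
    de_h, de_l = heavy.edges.shape[-1], light.edges.shape[-1]
    if dn_h != dn_l or de_h != de_l:
        raise ValueError("chain bundles have mismatched feature dimensions")
    Lh, Ll = heavy.length, light.length
    # gradient-preserving block assembly (zero blocks are constants)
    nodes = concat([heavy.nodes, light.nodes], axis=0)
    top = concat([heavy.edges, Tensor(np.zeros((Lh, Ll, de_h)))], axis=1)
    bottom = concat([Tensor(np.zeros((Ll, Lh, de_h))), light.edges], axis=1)
    edges = concat([top, bottom], axis=0)
    return EmbeddingBundle(nodes, edges, chain_boundary=Lh)


def unpair_chains(bundle: EmbeddingBundle
                  ) -> tuple[EmbeddingBundle, EmbeddingBundle | None]:
    """Inverse of :func:`pair_chains` (exact: pairing is information-preserving)."""
    Lh = bundle.chain_boundary
    L = bundle.length
    if Lh == L:
        return bundle, None
    nodes, edges = bundle.nodes.numpy(), bundle.edges.numpy()
    heavy = EmbeddingBundle(Tensor(nodes[:Lh].copy()),
                            Tensor(edges[:Lh, :Lh].copy()), Lh)
    light = EmbeddingBundle(Tensor(nodes[Lh:].copy()),
                            Tensor(edges[Lh:, Lh:].copy()), L - Lh)
    return heavy, light
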