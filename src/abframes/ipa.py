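"""Invariant point attention (IPA) in its three roles.

IPA mixes three attention signals: scalar query/key dot products, a
pairwise bias projected from the edge features, and the squared distances
between query/key points that each residue projects into its own rigid
frame and maps to global coordinates.  Because the point contribution
depends only on inter-point distances, and value points are mapped back
into each residue's local frame before the output projection, the node
update is invariant to any global rigid transform of the input frames.

Three uses:

* template encoder — two fixed-frame layers; attention is restricted to
  residue pairs that both carry template coordinates, and untemplated
  residues receive only the feed-forward transition update;
* structure module — frame-updating layers (separate weights per layer)
  that compose per-residue quaternion rotations and translations starting
  from all-identity frames at the origin, with gradients flowing through
  the rotation composition;
* error head — fixed-frame layers over the *final predicted* structure and
  a fresh projection of the initial language-model features, predicting
  non-negative per-residue deviations; the predicted frames enter as
  constants so no gradient reaches the structure-prediction weights.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concat, einsum, softmax, stack
from .config import ModelConfig
from .embeddings import EmbeddingBundle, LanguageModelOutput
from .geometry import FrameSet, IdealGeometry, frame_atoms_batch, frames_from_backbone
from .nn import LayerNorm, Linear, Module
from .structure import BackboneStructure

__all__ = ["IPALayer", "TemplateEncoder", "StructureModule", "ErrorHead"]

_NEG = -1e9


def _quat_to_rotmat(b: Tensor) -> Tensor:
    """(L, 3) unnormalized quaternion vector parts -> (L, 3, 3) rotations.

    Quaternion (1, b1, b2, b3) normalized to unit length; guarantees proper
    orthonormal output and smooth gradients near the identity.
    """
    L = b.shape[0]
    one = Tensor(np.ones(L))
    w, x, y, z = one, b[:, 0], b[:, 1], b[:, 2]
    norm = (w * w + x * x + y * y + z * z).sqrt()
    w, x, y, z = w / norm, x / norm, y / norm, z / norm
    r00 = 1.0 - 2.0 * (y * y + z * z)
    r01 = 2.0 * (x * y - w * z)
    r02 = 2.0 * (x * z + w * y)
    r10 = 2.0 * (x * y + w * z)
    r11 = 1.0 - 2.0 * (x * x + z * z)
    r12 = 2.0 * (y * z - w * x)
    r20 = 2.0 * (x * z - w * y)
    r21 = 2.0 * (y * z + w * x)
    r22 = 1.0 - 2.0 * (x * x + y * y)
    rows = [stack([r00, r01, r02], axis=-1),
            stack([r10, r11, r12], axis=-1),
            stack([r20, r21, r22], axis=-1)]
    return stack(rows, axis=1)


class IPALayer(Module):
    """One IPA layer: attention + feed-forward transition.

    mode="fixed": node update only.  mode="update": additionally emits a
    per-residue rigid update (quaternion + translation).
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator,
                 n_head: int, d_scalar: int, d_point: int, ff_dim: int,
                 ff_layers: int, mode: str = "fixed"):
        if mode not in ("fixed", "update"):
            raise ValueError("mode must be 'fixed' or 'update'")
        c_s, c_z = config.d_node, config.d_edge
        self.mode = mode
        self.n_head = n_head
        self.d_scalar = d_scalar
        self.n_qp = d_point                    # query/key points per head
        self.n_vp = config.n_value_points      # value points per head
        self.norm_s = LayerNorm(c_s)
        self.norm_z = LayerNorm(c_z)
        self.W_q = Linear(c_s, n_head * d_scalar, rng)
        self.W_k = Linear(c_s, n_head * d_scalar, rng)
        self.W_v = Linear(c_s, n_head * d_scalar, rng)
        self.W_qp = Linear(c_s, n_head * self.n_qp * 3, rng)
        self.W_kp = Linear(c_s, n_head * self.n_qp * 3, rng)
        self.W_vp = Linear(c_s, n_head * self.n_vp * 3, rng)
        self.W_b = Linear(c_z, n_head, rng)
        self.gamma_raw = Tensor(np.zeros(n_head) + math.log(math.e - 1.0),
                                requires_grad=True)  # softplus -> 1 at init
        concat_dim = n_head * (d_scalar + c_z + 3 * self.n_vp + self.n_vp)
        self.W_out = Linear(concat_dim, c_s, rng)
        self.norm_ff = LayerNorm(c_s)
        self.ff = [Linear(c_s if i == 0 else ff_dim,
                          ff_dim if i < ff_layers - 1 else c_s, rng)
                   for i in range(ff_layers)]
        if mode == "update":
            # small init so frames start near identity; translations are
            # predicted in units of trans_scale Å so weights stay O(1)
            self.trans_scale = 10.0
            self.W_upd = Linear(c_s, 6, rng, scale=1e-3)

    # -- helpers --------------------------------------------------------------
    def _transition(self, s: Tensor) -> Tensor:
        x = self.norm_ff(s)
        for i, lin in enumerate(self.ff):
            x = lin(x)
            if i < len(self.ff) - 1:
                x = x.relu()
        return s + x

    def __call__(self, nodes: Tensor, edges: Tensor,
                 rotations, translations,
                 pair_mask: np.ndarray | None = None):
        """Run one layer.

        `rotations` (L,3,3) and `translations` (L,3) may be Tensors (frame
        gradients flow) or arrays (treated as constants).  `pair_mask` is a
        boolean (L, L) array: attention only where True.  Rows with no
        allowed pair receive no attention update (transition only).
        """
        L = nodes.shape[0]
        H, ds = self.n_head, self.d_scalar
        if pair_mask is not None and not pair_mask.any():
            if self.mode == "update":
                raise ValueError("all pairs masked: nothing to attend")
            return self._transition(nodes)
        R = rotations if isinstance(rotations, Tensor) else Tensor(np.asarray(rotations))
        t = translations if isinstance(translations, Tensor) else Tensor(np.asarray(translations))

        sn = self.norm_s(nodes)
        zn = self.norm_z(edges)
        q = self.W_q(sn).reshape(L, H, ds)
        k = self.W_k(sn).reshape(L, H, ds)
        v = self.W_v(sn).reshape(L, H, ds)
        qp = self.W_qp(sn).reshape(L, H, self.n_qp, 3)
        kp = self.W_kp(sn).reshape(L, H, self.n_qp, 3)
        vp = self.W_vp(sn).reshape(L, H, self.n_vp, 3)
        bias = self.W_b(zn)  # (L, L, H)

        def to_global(p: Tensor) -> Tensor:
            return einsum("lij,lhpj->lhpi", R, p) + t.reshape(L, 1, 1, 3)

        qp_g, kp_g, vp_g = to_global(qp), to_global(kp), to_global(vp)
        diff = qp_g.reshape(L, 1, H, self.n_qp, 3) - kp_g.reshape(1, L, H, self.n_qp, 3)
        d2 = (diff * diff).sum(axis=(3, 4))            # (L, L, H)
        gamma = self.gamma_raw.softplus()              # (H,)
        w_l = math.sqrt(1.0 / 3.0)
        w_c = math.sqrt(2.0 / (9.0 * self.n_qp))
        logits = (einsum("ihd,jhd->ijh", q, k) / math.sqrt(ds) + bias
                  - gamma.reshape(1, 1, H) * (w_c / 2.0) * d2) * w_l
        if pair_mask is not None:
            logits = logits + Tensor(np.where(pair_mask, 0.0, _NEG)[:, :, None])
        alpha = softmax(logits, axis=1)                # (L, L, H)

        o_scalar = einsum("ijh,jhd->ihd", alpha, v).reshape(L, H * ds)
        o_pair = einsum("ijh,ijc->ihc", alpha, zn).reshape(L, H * zn.shape[-1])
        o_pt_g = einsum("ijh,jhpx->ihpx", alpha, vp_g)
        # back to each residue's local frame: R_i^T (o - t_i)
        rel = o_pt_g - t.reshape(L, 1, 1, 3)
        o_pt = einsum("lij,lhpi->lhpj", R, rel)
        o_norm = ((o_pt * o_pt).sum(axis=-1) + 1e-8).sqrt()
        o_cat = concat([o_scalar, o_pair,
                        o_pt.reshape(L, H * self.n_vp * 3),
                        o_norm.reshape(L, H * self.n_vp)], axis=-1)
        attn_out = self.W_out(o_cat)
        if pair_mask is not None:
            row_ok = pair_mask.any(axis=1).astype(float)[:, None]
            attn_out = attn_out * Tensor(row_ok)
        s = nodes + attn_out
        s = self._transition(s)
        if self.mode == "fixed":
            return s
        upd = self.W_upd(s)
        rot_upd = _quat_to_rotmat(upd[:, :3])
        tr_upd = upd[:, 3:] * self.trans_scale
        if not np.all(np.isfinite(upd.numpy())):
            raise FloatingPointError("non-finite frame update")
        new_R = einsum("lij,ljk->lik", R, rot_upd)
        new_t = einsum("lij,lj->li", R, tr_upd) + t
        return s, new_R, new_t


class TemplateEncoder(Module):
    """Fixed-frame IPA block incorporating (partial) template coordinates."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.layers = [
            IPALayer(config, rng, config.n_temp_head, config.d_temp_head_scalar,
                     config.d_temp_head_point, config.temp_ff_dim,
                     config.temp_ff_layers, mode="fixed")
            for _ in range(config.n_temp_layers)
        ]

    def __call__(self, nodes: Tensor, edges: Tensor,
                 template: BackboneStructure | None,
                 mask: np.ndarray | None = None) -> Tensor:
        if template is None:
            mask = np.zeros(nodes.shape[0], dtype=bool)
            frames = FrameSet.identity(nodes.shape[0])
        else:
            frames = frames_from_backbone(template)
            if mask is None:
                mask = np.ones(len(template), dtype=bool)
        pair = np.outer(mask, mask)
        for layer in self.layers:
            nodes = layer(nodes, edges, frames.rotations, frames.translations,
                          pair_mask=pair)
        return nodes


class StructureModule(Module):
    """Frame-predicting IPA block (separate weights per layer).

    All residue frames start at the identity with Cα at the origin; each
    layer composes a predicted rigid update, and the final frames place
    the four ideal frame atoms.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator,
                 geom: IdealGeometry | None = None):
        self.layers = [
            IPALayer(config, rng, config.n_str_head, config.d_str_head_scalar,
                     config.d_str_head_point, config.str_ff_dim,
                     config.str_ff_layers, mode="update")
            for _ in range(config.n_str_layers)
        ]
        self.geom = geom or IdealGeometry()

    def __call__(self, nodes: Tensor, edges: Tensor
                 ) -> tuple[Tensor, Tensor, Tensor]:
        """Returns (coords (L,4,3) Tensor, rotations, translations)."""
        L = nodes.shape[0]
        R = Tensor(np.tile(np.eye(3), (L, 1, 1)))
        t = Tensor(np.zeros((L, 3)))
        for i, layer in enumerate(self.layers):
            try:
                nodes, R, t = layer(nodes, edges, R, t)
            except FloatingPointError as err:
                raise FloatingPointError(f"structure layer {i}: {err}") from err
        coords = frame_atoms_batch(R, t, self.geom)
        return coords, R, t

    def frame_set(self, coords_or_R, t=None) -> FrameSet:
        R, tr = coords_or_R, t
        return FrameSet(np.asarray(R.numpy() if isinstance(R, Tensor) else R),
                        np.asarray(tr.numpy() if isinstance(tr, Tensor) else tr))


class ErrorHead(Module):
    """Per-residue deviation prediction from the final structure.

    Uses fresh affine projections of the *initial* language-model features
    (not the encoder output) and fixed-frame IPA over the predicted
    structure's frames.  Predicts deviations for all four frame atoms
    through a softplus map (non-negative); the Cα channel is the trained
    and reported estimate.  Frames are fitted from raw coordinates
    (constants in the graph), so gradients never reach the structure
    prediction weights.
    """

    CA_CHANNEL = 1  # storage order N, CA, C, CB

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.node_proj = Linear(config.lm_hidden_dim, config.d_node, rng)
        self.edge_proj = Linear(config.lm_attn_stack_dim, config.d_edge, rng)
        self.layers = [
            IPALayer(config, rng, config.n_err_head, config.d_err_head_scalar,
                     config.d_err_head_point, config.err_ff_dim,
                     config.err_ff_layers, mode="fixed")
            for _ in range(config.n_err_layers)
        ]
        self.out = Linear(config.d_node, 4, rng)
        self.config = config

    def features(self, lm_outs: list[LanguageModelOutput]) -> EmbeddingBundle:
        from .embeddings import pair_chains  # cycle guard
        bundles = []
        for lm in lm_outs:
            nodes = self.node_proj(Tensor(lm.hidden_states))
            edges = self.edge_proj(Tensor(lm.attention_stack))
            bundles.append(EmbeddingBundle(nodes, edges, len(lm.sequence)))
        combined = bundles[0]
        for extra in bundles[1:]:
            combined = pair_chains(combined, extra)
        return combined

    def __call__(self, lm_outs: list[LanguageModelOutput],
                 predicted: BackboneStructure) -> Tensor:
        bundle = self.features(lm_outs)
        frames = frames_from_backbone(predicted)  # numpy: stop-gradient
        nodes, edges = bundle.nodes, bundle.edges
        for layer in self.layers:
            nodes = layer(nodes, edges, frames.rotations, frames.translations)
        return self.out(nodes).softplus()  # (L, 4) non-negative deviations

    def ca_error(self, lm_outs: list[LanguageModelOutput],
                 predicted: BackboneStructure) -> Tensor:
        return self(lm_outs, predicted)[:, self.CA_CHANNEL]
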