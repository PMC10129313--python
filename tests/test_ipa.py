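"""Invariant point attention: oracle agreement, rigid invariance, masking,
frame-update differentiability, error-head stop-gradient."""

import math

import numpy as np
import pytest

from abframes.autodiff import Tensor
from abframes.config import ModelConfig
from abframes.embeddings import SyntheticEmbedder
from abframes.fixtures import ToySpec, make_toy_fv
from abframes.geometry import FrameSet, frames_from_backbone, random_rotation
from abframes.ipa import ErrorHead, IPALayer, StructureModule, TemplateEncoder
from abframes.model import StructurePredictor

RNG = np.random.default_rng(23)


def tiny_cfg(**kw):
    defaults = dict(d_node=6, d_edge=5, n_value_points=3)
    defaults.update(kw)
    return ModelConfig(**defaults)


def make_layer(cfg, mode="fixed", heads=2, ds=4, dp=2, ff=7, ff_layers=3,
               seed=0):
    return IPALayer(cfg, np.random.default_rng(seed), heads, ds, dp, ff,
                    ff_layers, mode=mode)


def random_frames(L, rng, spread=8.0):
    R = np.stack([random_rotation(rng) for _ in range(L)])
    t = rng.normal(scale=spread, size=(L, 3))
    return R, t


def _ln(x, g, o, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    var = ((x - mu) ** 2).mean(-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * g + o


def ipa_oracle(layer: IPALayer, s: np.ndarray, z: np.ndarray,
               R: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Loop transcription of the cited invariant-point-attention algorithm:
    scalar queries/keys, pair bias, squared-distance penalty between
    frame-projected points, value/pair/point outputs with point norms,
    then the feed-forward transition."""
    L, H, ds = s.shape[0], layer.n_head, layer.d_scalar
    nqp, nvp = layer.n_qp, layer.n_vp
    sn = _ln(s, layer.norm_s.g.numpy(), layer.norm_s.o.numpy())
    zn = _ln(z, layer.norm_z.g.numpy(), layer.norm_z.o.numpy())

    def lin(W, x):
        return x @ W.W.numpy() + W.b.numpy()

    q = lin(layer.W_q, sn).reshape(L, H, ds)
    k = lin(layer.W_k, sn).reshape(L, H, ds)
    v = lin(layer.W_v, sn).reshape(L, H, ds)
    qp = lin(layer.W_qp, sn).reshape(L, H, nqp, 3)
    kp = lin(layer.W_kp, sn).reshape(L, H, nqp, 3)
    vp = lin(layer.W_vp, sn).reshape(L, H, nvp, 3)
    bias = lin(layer.W_b, zn)
    gamma = np.log1p(np.exp(layer.gamma_raw.numpy()))
    w_l = math.sqrt(1.0 / 3.0)
    w_c = math.sqrt(2.0 / (9.0 * nqp))
    out_rows = []
    for i in range(L):
        per_head = []
        for h in range(H):
            logits = np.zeros(L)
            for j in range(L):
                qg = np.array([R[i] @ qp[i, h, p] + t[i] for p in range(nqp)])
                kg = np.array([R[j] @ kp[j, h, p] + t[j] for p in range(nqp)])
                d2 = np.sum((qg - kg) ** 2)
                logits[j] = w_l * (q[i, h] @ k[j, h] / math.sqrt(ds)
                                   + bias[i, j, h]
                                   - gamma[h] * w_c / 2.0 * d2)
            a = np.exp(logits - logits.max())
            a /= a.sum()
            o_s = sum(a[j] * v[j, h] for j in range(L))
            o_z = sum(a[j] * zn[i, j] for j in range(L))
            o_p_g = np.zeros((nvp, 3))
            for j in range(L):
                for p in range(nvp):
                    o_p_g[p] += a[j] * (R[j] @ vp[j, h, p] + t[j])
            o_p = np.array([R[i].T @ (o_p_g[p] - t[i]) for p in range(nvp)])
            o_n = np.sqrt(np.sum(o_p ** 2, axis=1) + 1e-8)
            per_head.append(np.concatenate([o_s, o_z, o_p.ravel(), o_n]))
        # heads concatenated feature-block-wise: scalars, pair, points, norms
        blocks = [np.concatenate([ph[a:b] for ph in per_head])
                  for a, b in [(0, ds), (ds, ds + zn.shape[-1]),
                               (ds + zn.shape[-1], ds + zn.shape[-1] + nvp * 3),
                               (ds + zn.shape[-1] + nvp * 3,
                                ds + zn.shape[-1] + nvp * 4)]]
        out_rows.append(np.concatenate(blocks))
    o_cat = np.stack(out_rows)
    s1 = s + lin(layer.W_out, o_cat)
    x = _ln(s1, layer.norm_ff.g.numpy(), layer.norm_ff.o.numpy())
    for li, linear in enumerate(layer.ff):
        x = lin(linear, x)
        if li < len(layer.ff) - 1:
            x = np.maximum(x, 0.0)
    return s1 + x


class TestIPALayer:
    def test_matches_independent_oracle(self):
        cfg = tiny_cfg()
        layer = make_layer(cfg)
        L = 4
        s = RNG.normal(size=(L, 6))
        z = RNG.normal(size=(L, L, 5))
        R, t = random_frames(L, RNG)
        got = layer(Tensor(s), Tensor(z), R, t).numpy()
        np.testing.assert_allclose(got, ipa_oracle(layer, s, z, R, t),
                                   atol=1e-5)

    def test_invariant_to_global_rigid_transform(self):
        cfg = tiny_cfg()
        layer = make_layer(cfg)
        L = 5
        s = RNG.normal(size=(L, 6))
        z = RNG.normal(size=(L, L, 5))
        R, t = random_frames(L, RNG)
        base = layer(Tensor(s), Tensor(z), R, t).numpy()
        G = random_rotation(RNG)
        g = RNG.normal(scale=20.0, size=3)
        R2 = np.einsum("ij,ljk->lik", G, R)
        t2 = t @ G.T + g
        moved = layer(Tensor(s), Tensor(z), R2, t2).numpy()
        np.testing.assert_allclose(moved, base, atol=1e-4)

    def test_fully_masked_equals_transition_only(self):
        cfg = tiny_cfg()
        layer = make_layer(cfg)
        L = 4
        s = Tensor(RNG.normal(size=(L, 6)))
        z = Tensor(RNG.normal(size=(L, L, 5)))
        R, t = random_frames(L, RNG)
        masked = layer(s, z, R, t, pair_mask=np.zeros((L, L), bool))
        np.testing.assert_allclose(masked.numpy(),
                                   layer._transition(s).numpy(), atol=1e-12)

    def test_update_mode_with_all_masked_raises(self):
        cfg = tiny_cfg()
        layer = make_layer(cfg, mode="update")
        L = 3
        with pytest.raises(ValueError, match="masked"):
            layer(Tensor(RNG.normal(size=(L, 6))),
                  Tensor(RNG.normal(size=(L, L, 5))),
                  *random_frames(L, RNG), pair_mask=np.zeros((L, L), bool))


class TestTemplateEncoder:
    def _setup(self, L_cfg=tiny_cfg):
        cfg = tiny_cfg(n_temp_layers=2, n_temp_head=2, d_temp_head_scalar=4,
                       d_temp_head_point=2, temp_ff_dim=7)
        enc = TemplateEncoder(cfg, np.random.default_rng(3))
        native = make_toy_fv(ToySpec(seed=4))
        L = len(native)
        s = RNG.normal(size=(L, 6))
        z = RNG.normal(size=(L, L, 5))
        return enc, native, s, z

    def test_no_template_equals_transitions_only(self):
        enc, native, s, z = self._setup()
        got = enc(Tensor(s), Tensor(z), None).numpy()
        expected = Tensor(s)
        for layer in enc.layers:
            expected = layer._transition(expected)
        np.testing.assert_allclose(got, expected.numpy(), atol=1e-12)

    def test_invariant_to_rigid_motion_of_template(self):
        enc, native, s, z = self._setup()
        base = enc(Tensor(s), Tensor(z), native).numpy()
        moved = native.transformed(random_rotation(RNG),
                                   RNG.normal(scale=15.0, size=3))
        got = enc(Tensor(s), Tensor(z), moved).numpy()
        np.testing.assert_allclose(got, base, atol=1e-4)

    def test_masked_residues_do_not_influence_distant_outputs(self):
        enc, native, s, z = self._setup()
        mask = np.ones(len(native), bool)
        h3 = (native.regions == "CDR3") & (native.chain_ids == "H")
        mask[h3] = False
        base = enc(Tensor(s), Tensor(z), native, mask).numpy()
        altered = native.copy()
        altered.coords[h3] += RNG.normal(scale=4.0, size=(h3.sum(), 4, 3))
        got = enc(Tensor(s), Tensor(z), altered, mask).numpy()
        probe = np.flatnonzero(~mask[: len(native)] == False)  # unmasked rows
        np.testing.assert_allclose(got[mask], base[mask], atol=1e-6)


class TestStructureModule:
    def _module(self, seed=0):
        cfg = tiny_cfg(n_str_layers=3, n_str_head=2, d_str_head_scalar=4,
                       d_str_head_point=2, str_ff_dim=7)
        return StructureModule(cfg, np.random.default_rng(seed))

    def test_zero_update_weights_keep_residues_at_origin(self):
        sm = self._module()
        for layer in sm.layers:
            layer.W_upd.W.data[:] = 0
            layer.W_upd.b.data[:] = 0
        L = 4
        s = Tensor(RNG.normal(size=(L, 6)))
        z = Tensor(RNG.normal(size=(L, L, 5)))
        coords, R, t = sm(s, z)
        np.testing.assert_allclose(t.numpy(), 0.0, atol=1e-12)
        local = coords.numpy()[0]
        for i in range(L):
            np.testing.assert_allclose(coords.numpy()[i], local, atol=1e-12)

    def test_output_rotations_orthonormal(self):
        sm = self._module()
        L = 5
        coords, R, t = sm(Tensor(RNG.normal(size=(L, 6))),
                          Tensor(RNG.normal(size=(L, L, 5))))
        Rn = R.numpy()
        for i in range(L):
            np.testing.assert_allclose(Rn[i].T @ Rn[i], np.eye(3), atol=1e-5)
            assert np.linalg.det(Rn[i]) > 0

    def test_gradients_flow_through_rotations(self):
        """Finite differences on a first-layer weight must match autodiff,
        confirming the rotation composition is differentiated."""
        sm = self._module()
        L = 3
        s_np = RNG.normal(size=(L, 6))
        z_np = RNG.normal(size=(L, L, 5))
        w = RNG.normal(size=(L, 4, 3))

        def objective():
            coords, _, _ = sm(Tensor(s_np), Tensor(z_np))
            return (coords * Tensor(w)).sum()

        param = sm.layers[0].W_qp.W
        loss = objective()
        loss.backward()
        g_auto = param.grad.copy()
        eps = 1e-5
        idx = (2, 1)
        param.data[idx] += eps
        up = objective().item()
        param.data[idx] -= 2 * eps
        dn = objective().item()
        param.data[idx] += eps
        g_num = (up - dn) / (2 * eps)
        assert g_auto[idx] == pytest.approx(g_num, rel=1e-4, abs=1e-8)

    def test_deterministic(self):
        sm = self._module()
        L = 4
        s = Tensor(RNG.normal(size=(L, 6)))
        z = Tensor(RNG.normal(size=(L, L, 5)))
        c1, _, _ = sm(s, z)
        c2, _, _ = sm(s, z)
        np.testing.assert_array_equal(c1.numpy(), c2.numpy())


class TestErrorHead:
    def _head_inputs(self, toy_config):
        head_cfg = ModelConfig.toy()
        head = ErrorHead(head_cfg, np.random.default_rng(5))
        emb = SyntheticEmbedder(head_cfg, 0)
        native = make_toy_fv(ToySpec(seed=6))
        h = len(native.chain_indices("H"))
        lm = [emb(native.sequence[:h]), emb(native.sequence[h:])]
        return head, lm, native

    def test_outputs_non_negative(self, toy_config):
        head, lm, native = self._head_inputs(toy_config)
        err = head(lm, native).numpy()
        assert err.shape == (len(native), 4)
        assert np.all(err >= 0)

    def test_invariant_to_rigid_motion_of_prediction(self, toy_config):
        head, lm, native = self._head_inputs(toy_config)
        base = head.ca_error(lm, native).numpy()
        moved = native.transformed(random_rotation(RNG),
                                   RNG.normal(scale=30.0, size=3))
        got = head.ca_error(lm, moved).numpy()
        np.testing.assert_allclose(got, base, atol=1e-4)

    def test_stop_gradient_into_structure_module(self, toy_config):
        """The mean predicted error must have exactly zero gradient w.r.t.
        every encoder / structure-module / projector parameter."""
        model = StructurePredictor(ModelConfig.toy(), seed=2)
        emb = SyntheticEmbedder(model.config, 0)
        native = make_toy_fv(ToySpec(seed=6))
        h = len(native.chain_indices("H"))
        lm = [emb(native.sequence[:h]), emb(native.sequence[h:])]
        result = model.forward(lm)
        model.zero_grad()
        result.pred_error_all.mean().backward()
        for name, p in model.parameters().items():
            if name.startswith("error_head"):
                continue
            assert p.grad is None or not np.any(p.grad), name
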