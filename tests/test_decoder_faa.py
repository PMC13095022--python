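"""Gated axial attention and the decoder path."""

import numpy as np
import pytest

from dscanet import autodiff as ad
from dscanet import nn
from dscanet.autodiff import Tensor
from dscanet.decoder_faa import (Decoder, DecoderConfig, FAABlock,
                                 GatedAxialAttention1D)


def gated_axial_oracle(q, k, v, r_q, r_k, r_v, gates, scale):
    """Three-loop direct evaluation of the gated width-axis attention for
    one head: q,k,v are (L, d); r_* are (L, L, d) offset tables."""
    g_q, g_k, g_v1, g_v2 = gates
    L, d = q.shape
    out = np.zeros_like(v)
    for i in range(L):
        logits = np.zeros(L)
        for w in range(L):
            logits[w] = q[i] @ k[w] * scale + g_q * (q[i] @ r_q[i, w]) \
                + g_k * (k[w] @ r_k[i, w])
        e = np.exp(logits - logits.max())
        a = e / e.sum()
        for w in range(L):
            out[i] += a[w] * (g_v1 * v[w] + g_v2 * r_v[i, w])
    return out


def _extract_qkv(layer, x):
    """Run the qkv projection and split into per-head (L, d) arrays for a
    1×C×1×L width-axis input, single head."""
    qkv = layer.qkv(x).data  # (1, 3C, 1, L)
    C = layer.dim
    q = qkv[0, :C, 0, :].T
    k = qkv[0, C:2 * C, 0, :].T
    v = qkv[0, 2 * C:, 0, :].T
    return q, k, v


class TestGatedAxialAttention:
    def test_matches_three_loop_oracle(self, param_rng, rng):
        layer = GatedAxialAttention1D(4, 1, "width", param_rng, max_axis=8)
        x = Tensor(rng.normal(size=(1, 4, 1, 4)).astype(np.float32))
        with ad.no_grad():
            out = layer(x)
        q, k, v = _extract_qkv(layer, x)
        L, d = 4, 4
        rows = layer.relpos.offsets(L)
        r_q = layer.relpos.r_q.data[rows]
        r_k = layer.relpos.r_k.data[rows]
        r_v = layer.relpos.r_v.data[rows]
        gates = [float(getattr(layer.gates, g).data)
                 for g in ("g_q", "g_k", "g_v1", "g_v2")]
        ref = gated_axial_oracle(q.astype(np.float64), k.astype(np.float64),
                                 v.astype(np.float64), r_q, r_k, r_v, gates,
                                 scale=d ** -0.5)
        ref = ad.conv2d(Tensor(ref.T[None, :, None, :].astype(np.float32)),
                        layer.proj.weight, layer.proj.bias).data
        np.testing.assert_allclose(out.data, ref, rtol=1e-4, atol=1e-5)

    def test_axis_length_one_collapses_softmax(self, param_rng, rng):
        layer = GatedAxialAttention1D(4, 1, "width", param_rng, max_axis=8)
        x = Tensor(rng.normal(size=(1, 4, 3, 1)).astype(np.float32))
        with ad.no_grad():
            out = layer(x)
        q, k, v = None, None, None
        qkv = layer.qkv(x).data
        v = qkv[:, 8:, :, :]
        r_v0 = layer.relpos.r_v.data[layer.relpos.max_axis - 1]  # offset 0
        g1 = float(layer.gates.g_v1.data)
        g2 = float(layer.gates.g_v2.data)
        y = g1 * v[0, :, :, 0].T + g2 * r_v0[None, :]
        ref = ad.conv2d(Tensor(y.T[None, :, :, None]), layer.proj.weight,
                        layer.proj.bias).data
        np.testing.assert_allclose(out.data, ref, rtol=1e-4, atol=1e-5)

    def test_zero_value_gates_zero_output(self, param_rng, rng):
        layer = GatedAxialAttention1D(4, 2, "height", param_rng, max_axis=8)
        layer.gates.g_v1.data = np.float32(0.0)
        layer.gates.g_v2.data = np.float32(0.0)
        layer.proj.bias.data[:] = 0
        x = Tensor(rng.normal(size=(1, 4, 5, 3)).astype(np.float32))
        with ad.no_grad():
            np.testing.assert_allclose(layer(x).data, 0.0, atol=1e-6)

    def test_positional_gates_off_reduces_to_plain_axial(self, param_rng, rng):
        """With G_Q = G_K = 0 and G_V2 = 0 the layer equals unpositioned
        axial attention scaled by G_V1."""
        layer = GatedAxialAttention1D(4, 1, "width", param_rng, max_axis=8)
        for g in ("g_q", "g_k", "g_v2"):
            getattr(layer.gates, g).data = np.float32(0.0)
        layer.gates.g_v1.data = np.float32(1.0)
        x = Tensor(rng.normal(size=(1, 4, 1, 5)).astype(np.float32))
        with ad.no_grad():
            out = layer(x)
        q, k, v = _extract_qkv(layer, x)
        L, d = 5, 4
        ref = np.zeros_like(v)
        for i in range(L):
            logits = np.array([q[i] @ k[w] * d ** -0.5 for w in range(L)])
            e = np.exp(logits - logits.max())
            ref[i] = (e / e.sum()) @ v
        ref = ad.conv2d(Tensor(ref.T[None, :, None, :].astype(np.float32)),
                        layer.proj.weight, layer.proj.bias).data
        np.testing.assert_allclose(out.data, ref, rtol=1e-4, atol=1e-5)

    def test_height_axis_output_depends_only_on_own_column(self, param_rng, rng):
        layer = GatedAxialAttention1D(2, 1, "height", param_rng, max_axis=8)
        x = rng.normal(size=(1, 2, 5, 5)).astype(np.float32)
        with ad.no_grad():
            base = layer(Tensor(x)).data
            y = x.copy()
            y[0, :, 2, 3] += 1.0  # perturb column 3
            pert = layer(Tensor(y)).data
        diff = np.abs(pert - base).sum(axis=(0, 1, 2))
        assert diff[3] > 1e-4
        np.testing.assert_allclose(diff[[0, 1, 2, 4]], 0.0, atol=1e-5)


class TestFAABlock:
    def test_shape_preserved_for_rectangular_input(self, param_rng, rng):
        blk = FAABlock(4, 2, param_rng, max_axis=16)
        blk.eval()
        x = Tensor(rng.normal(size=(2, 4, 5, 9)).astype(np.float32))
        with ad.no_grad():
            assert blk(x).shape == (2, 4, 5, 9)

    def test_zero_projections_make_identity(self, param_rng, rng):
        blk = FAABlock(4, 2, param_rng, max_axis=8)
        blk.eval()
        for attn in (blk.attn_h, blk.attn_w):
            attn.proj.weight.data[:] = 0
            attn.proj.bias.data[:] = 0
        x = rng.normal(size=(1, 4, 3, 3)).astype(np.float32)
        with ad.no_grad():
            np.testing.assert_allclose(blk(Tensor(x)).data, x, atol=1e-6)

    def test_two_axis_composition_is_global(self, param_rng, rng):
        """After height-then-width attention every output position feels a
        perturbation at any single input position."""
        blk = FAABlock(2, 1, param_rng, max_axis=8)
        blk.eval()
        x = rng.normal(size=(1, 2, 5, 5)).astype(np.float32)
        with ad.no_grad():
            base = blk(Tensor(x)).data
            y = x.copy()
            y[0, 0, 1, 4] += 0.5
            pert = blk(Tensor(y)).data
        diff = np.abs(pert - base).sum(axis=(0, 1))
        assert (diff > 1e-9).all()


class TestDecoder:
    def _pyramid(self, rng, widths=(8, 16, 32, 64), size=32):
        return [Tensor(rng.normal(size=(1, w, size // (4 * 2 ** i),
                                        size // (4 * 2 ** i))).astype(np.float32))
                for i, w in enumerate(widths)]

    def test_logit_map_at_input_resolution(self, param_rng, rng):
        cfg = DecoderConfig(widths=(32, 16, 16, 8), refine_widths=(8, 8),
                            heads=2, max_axis=16)
        dec = Decoder([8, 16, 32, 64], cfg, param_rng)
        dec.eval()
        with ad.no_grad():
            out = dec(self._pyramid(rng), (32, 32))
        assert out.shape == (1, 1, 32, 32)

    def test_runs_without_faa(self, param_rng, rng):
        cfg = DecoderConfig(widths=(32, 16, 16, 8), refine_widths=(8, 8), heads=2)
        dec = Decoder([8, 16, 32, 64], cfg, param_rng, use_faa=False)
        dec.eval()
        with ad.no_grad():
            out = dec(self._pyramid(rng), (32, 32))
        assert out.shape == (1, 1, 32, 32)
        assert not any(k.startswith("faa") for k, _ in dec.named_parameters())

    def test_eval_mode_deterministic(self, param_rng, rng):
        cfg = DecoderConfig(widths=(16, 16, 8, 8), refine_widths=(8, 8), heads=2)
        dec = Decoder([8, 16, 32, 64], cfg, param_rng)
        dec.eval()
        pyr = self._pyramid(rng)
        with ad.no_grad():
            a = dec(pyr, (32, 32)).data
            b = dec(pyr, (32, 32)).data
        np.testing.assert_array_equal(a, b)
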