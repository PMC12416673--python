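"""Harmonic connectivity, RFB, aggregation and the full model contract."""

import numpy as np
import pytest

from hardvessel import nn
from hardvessel.nn import Tensor
from hardvessel.network import (
    RFB,
    Aggregator,
    HardBlock,
    HardBlockSpec,
    ModelConfig,
    build_model,
    count_parameters,
    hard_block_channels,
    hard_block_links,
)
from hardvessel.objective import total_loss


def brute_force_links(k):
    return {k - 2**n for n in range(k.bit_length() + 1) if k % 2**n == 0}


def brute_force_channels(k, growth, mult):
    p = max(n for n in range(k.bit_length() + 1) if k % 2**n == 0)
    return 2 * int((growth * mult**p) / 2)


class TestHarmonicRule:
    @pytest.mark.parametrize("k,expected", [(1, {0}), (6, {5, 4}),
                                            (8, {7, 6, 4, 0})])
    def test_link_examples(self, k, expected):
        assert hard_block_links(k) == expected

    @pytest.mark.parametrize("k,growth,mult,expected", [
        (1, 16, 1.7, 16), (3, 16, 1.7, 16),   # odd layers keep the growth
        (2, 16, 1.7, 26),                      # 16·1.7 = 27.2 → 26
        (4, 16, 1.7, 46),                      # 16·1.7² = 46.24 → 46
    ])
    def test_channel_examples(self, k, growth, mult, expected):
        assert hard_block_channels(k, growth, mult) == expected

    @pytest.mark.parametrize("growth,mult", [(10, 1.7), (16, 1.7), (18, 1.6),
                                             (24, 2.0), (12, 1.0)])
    def test_exhaustive_enumeration_k_1_to_32(self, growth, mult):
        for k in range(1, 33):
            assert hard_block_links(k) == brute_force_links(k)
            assert hard_block_channels(k, growth, mult) == \
                brute_force_channels(k, growth, mult)

    def test_invalid_layer_index(self):
        with pytest.raises(ValueError):
            hard_block_links(0)
        with pytest.raises(ValueError):
            hard_block_channels(0, 16, 1.7)


class TestHardBlock:
    def test_output_concatenates_last_and_odd_layers(self):
        spec = HardBlockSpec.from_rule(4, 10, 1.7, in_channels=8)
        assert spec.out_layers == [1, 3, 4]
        assert spec.out_channels == sum(spec.layer_channels[k]
                                        for k in (1, 3, 4))
        rng = np.random.default_rng(0)
        block = HardBlock(spec, rng)
        y = block(Tensor(rng.random((1, 8, 12, 12)).astype(np.float32)))
        assert y.shape == (1, spec.out_channels, 12, 12)

    def test_single_layer_block(self):
        spec = HardBlockSpec.from_rule(1, 10, 1.7, in_channels=4)
        assert spec.out_channels == spec.layer_channels[1]
        block = HardBlock(spec, np.random.default_rng(0))
        y = block(Tensor(np.zeros((1, 4, 8, 8), np.float32)))
        assert y.shape == (1, spec.out_channels, 8, 8)

    def test_spatial_dims_preserved(self):
        spec = HardBlockSpec.from_rule(8, 18, 1.7, in_channels=16)
        block = HardBlock(spec, np.random.default_rng(1))
        y = block(Tensor(np.zeros((2, 16, 10, 14), np.float32)))
        assert y.shape[2:] == (10, 14)

    def test_channel_mismatch_raises(self):
        spec = HardBlockSpec.from_rule(2, 10, 1.7, in_channels=8)
        block = HardBlock(spec, np.random.default_rng(0))
        with pytest.raises(ValueError, match="channels"):
            block(Tensor(np.zeros((1, 5, 8, 8), np.float32)))


class TestRFB:
    def test_shape_contract(self):
        rfb = RFB(24, 16, np.random.default_rng(0))
        y = rfb(Tensor(np.zeros((2, 24, 20, 20), np.float32)))
        assert y.shape == (2, 16, 20, 20)

    def test_dilated_branch_enlarges_receptive_field(self):
        """The gradient footprint of one output pixel must span at least
        11×11 input pixels through the dilation-5 branch, versus 3×3 for a
        single plain convolution."""
        rfb = RFB(4, 8, np.random.default_rng(3))
        x = np.random.default_rng(0).random((1, 4, 21, 21)).astype(np.float32)
        t = Tensor(x, requires_grad=True)
        y = rfb(t)
        y[0, :, 10, 10].sum().backward()
        footprint = np.abs(t.grad).sum(axis=(0, 1)) > 0
        rows = np.flatnonzero(footprint.any(axis=1))
        cols = np.flatnonzero(footprint.any(axis=0))
        assert rows[-1] - rows[0] + 1 >= 11
        assert cols[-1] - cols[0] + 1 >= 11


class TestAggregator:
    def _maps(self, c=6, h=16):
        rng = np.random.default_rng(2)
        return [Tensor(rng.random((1, c, h // f, h // f)).astype(np.float32))
                for f in (1, 2, 4)]

    def test_logits_at_finest_scale(self):
        agg = Aggregator(6, np.random.default_rng(0))
        y = agg(self._maps())
        assert y.shape == (1, 1, 16, 16)

    def test_non_dyadic_chain_rejected(self):
        agg = Aggregator(6, np.random.default_rng(0))
        maps = self._maps()
        maps[1] = Tensor(np.zeros((1, 6, 7, 7), np.float32))
        with pytest.raises(ValueError, match="dyadic"):
            agg(maps)

    def test_upsampled_constants_fuse_to_constant(self):
        # multiplicative fusion of constant streams stays constant before
        # any border-padded convolution touches it
        a = Tensor(np.full((1, 3, 8, 8), 2.0))
        b = Tensor(np.full((1, 3, 4, 4), 3.0))
        fused = nn.bilinear_resize(b, 8, 8) * a
        np.testing.assert_allclose(fused.data, 6.0)


class TestModelForward:
    @pytest.mark.parametrize("variant", ["baseline", "hard", "rfb", "full"])
    def test_all_variants_run_on_64px_input(self, variant):
        model = build_model({"variant": variant, "seed": 1})
        x = np.random.default_rng(0).random((1, 3, 64, 64),
                                            dtype=np.float32)
        y = model.predict_proba(x)
        assert y.shape == (1, 1, 64, 64)
        assert (y >= 0).all() and (y <= 1).all()

    def test_input_not_multiple_of_32_is_padded_and_cropped(self):
        model = build_model({"seed": 1})
        x = np.random.default_rng(0).random((1, 3, 72, 104),
                                            dtype=np.float32)
        y = model.predict_proba(x)
        assert y.shape == (1, 1, 72, 104)

    def test_batch_permutation_equivariance(self):
        model = build_model({"seed": 3}).eval()
        x = np.random.default_rng(1).random((3, 3, 64, 64),
                                            dtype=np.float32)
        y = model.predict_proba(x)
        y_perm = model.predict_proba(x[[2, 0, 1]])
        np.testing.assert_allclose(y_perm, y[[2, 0, 1]], atol=1e-6)

    def test_forward_deterministic_given_weights(self):
        model = build_model({"seed": 5}).eval()
        x = np.random.default_rng(2).random((1, 3, 64, 64),
                                            dtype=np.float32)
        np.testing.assert_array_equal(model.predict_proba(x),
                                      model.predict_proba(x))

    def test_bad_input_shape_raises(self):
        model = build_model({"seed": 1})
        with pytest.raises(ValueError, match="N×3×H×W"):
            model.forward(np.zeros((1, 1, 64, 64), np.float32))

    def test_deep_supervision_returns_aux_maps(self):
        model = build_model({"seed": 1, "deep_supervision": True})
        x = np.random.default_rng(0).random((1, 3, 64, 64),
                                            dtype=np.float32)
        outs = model.forward(x)
        assert isinstance(outs, list) and len(outs) == 4
        for o in outs:
            assert o.shape == (1, 1, 64, 64)

    def test_gradients_finite_through_whole_graph(self):
        model = build_model({"seed": 7})
        rng = np.random.default_rng(0)
        x = rng.random((2, 3, 64, 64), dtype=np.float32)
        g = (rng.random((2, 1, 64, 64)) > 0.9).astype(np.float32)
        out = model.forward(x)
        loss, _ = total_loss(out, g)
        loss.backward()
        for name, p in model.named_parameters():
            assert p.grad is not None and np.isfinite(p.grad).all(), name


class TestCountParameters:
    def test_single_conv_closed_form(self):
        conv = nn.Conv2d(3, 8, 3, rng=np.random.default_rng(0))
        assert count_parameters(conv) == 3 * 3 * 3 * 8 + 8

    def test_freezing_all_parameters_counts_zero(self):
        model = build_model({"seed": 1})
        for p in model.parameters():
            p.requires_grad = False
        assert count_parameters(model) == 0

    def test_count_invariant_to_input_size(self):
        model = build_model({"seed": 1})
        n = count_parameters(model)
        model.predict_proba(np.zeros((1, 3, 64, 64), np.float32))
        model.predict_proba(np.zeros((1, 3, 96, 96), np.float32))
        assert count_parameters(model) == n


def test_invalid_variant_rejected():
    with pytest.raises(ValueError, match="variant"):
        ModelConfig(variant="bogus").validate()
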