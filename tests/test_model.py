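"""Architecture contracts: shapes, parameter counts, residual identities,
ablation behaviour, and determinism of the hybrid U-Net."""

import numpy as np
import pytest

from hybridseg.autodiff import Tensor, no_grad
from hybridseg.model import (
    ArchitectureConfig,
    ConfigurationError,
    ConvSpec,
    HybridUNet,
    ResidualBlock,
    ShapeError,
    binarize,
    conv_param_count,
    count_parameters,
)
from hybridseg import nn


class TestConvParamCount:
    @pytest.mark.parametrize(
        "spec,expected",
        [
            (ConvSpec(cin=32, cout=1, k=1, bias=True), 33),   # the output head
            (ConvSpec(cin=3, cout=32, k=3, bias=False), 864),
            (ConvSpec(cin=1, cout=1, k=1, bias=True), 2),
        ],
    )
    def test_examples(self, spec, expected):
        assert conv_param_count(spec) == expected

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            conv_param_count(ConvSpec(cin=0, cout=4, k=3))


class TestResidualBlock:
    def test_identity_when_weights_zeroed_and_input_nonnegative(self, rng):
        block = ResidualBlock(4, 4, rng)
        for _, p in block.named_parameters():
            if p.data.ndim == 4:          # conv weights
                p.data = np.zeros_like(p.data)
        # batch norm at init is the identity in eval mode (mean 0, var 1)
        block.eval()
        x = np.abs(rng.standard_normal((1, 4, 5, 5))).astype(np.float32)
        out = block(Tensor(x))
        np.testing.assert_allclose(out.data, x, rtol=1e-5)

    def test_shape_preserved_and_projection_path(self, rng):
        block = ResidualBlock(3, 8, rng)
        out = block(Tensor(rng.standard_normal((1, 3, 6, 6)).astype(np.float32)))
        assert out.shape == (1, 8, 6, 6)
        assert block.proj is not None
        same = ResidualBlock(8, 8, rng)
        assert same.proj is None

    def test_channel_mismatch_rejected(self, rng):
        block = ResidualBlock(4, 4, rng)
        with pytest.raises(ShapeError):
            block(Tensor(np.zeros((1, 3, 5, 5), dtype=np.float32)))

    def test_matches_explicit_composition_oracle(self, rng):
        """Brute-force recomputation of ReLU(BN(conv)) -> BN(conv) -> +skip."""
        block = ResidualBlock(4, 4, rng)
        block.eval()
        x = rng.standard_normal((1, 4, 5, 5)).astype(np.float32)

        def conv(inp, w):  # plain dense cross-correlation, pad 1
            _, C, H, W = inp.shape
            Cout = w.shape[0]
            pad = np.pad(inp, ((0, 0), (0, 0), (1, 1), (1, 1)))
            out = np.zeros((1, Cout, H, W))
            for c in range(Cout):
                for i in range(H):
                    for j in range(W):
                        out[0, c, i, j] = (pad[0, :, i : i + 3, j : j + 3] * w[c]).sum()
            return out

        def bn(inp, layer):
            m = layer.running_mean.reshape(1, -1, 1, 1)
            v = layer.running_var.reshape(1, -1, 1, 1)
            g = layer.weight.data.reshape(1, -1, 1, 1)
            b = layer.bias.data.reshape(1, -1, 1, 1)
            return (inp - m) / np.sqrt(v + layer.eps) * g + b

        y = np.maximum(bn(conv(x, block.conv1.weight.data), block.bn1), 0)
        z = bn(conv(y, block.conv2.weight.data), block.bn2)
        expected = np.maximum(z + x, 0)
        got = block(Tensor(x)).data
        np.testing.assert_allclose(got, expected, rtol=1e-4, atol=1e-5)


class TestEncoderAndForward:
    def test_stage_channels_and_spatial_halving(self, tiny_model):
        x = np.random.default_rng(0).random((1, 3, 32, 32)).astype(np.float32)
        tiny_model.eval()
        with no_grad():
            tiny_model(x, record=True)
        trace = tiny_model.last_trace
        assert [trace[f"encoder_skip_{i}"][1] for i in (1, 2, 3, 4)] == [4, 8, 16, 32]
        assert trace["encoder_bottom"] == (1, 32, 2, 2)
        assert trace["bottleneck"] == (1, 64, 2, 2)
        assert trace["logits"] == (1, 1, 32, 32)

    def test_indivisible_input_rejected(self, tiny_model):
        with pytest.raises(ConfigurationError):
            tiny_model(np.zeros((1, 3, 30, 30), dtype=np.float32))

    def test_wrong_channel_count_rejected(self, tiny_model):
        with pytest.raises(ShapeError):
            tiny_model(np.zeros((1, 1, 32, 32), dtype=np.float32))

    def test_probabilities_in_unit_interval(self, tiny_model, rng):
        out = tiny_model(rng.standard_normal((2, 3, 32, 32)).astype(np.float32))
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_zeroed_head_gives_exactly_half(self, tiny_model, rng):
        tiny_model.head.weight.data = np.zeros_like(tiny_model.head.weight.data)
        tiny_model.head.bias.data = np.zeros_like(tiny_model.head.bias.data)
        tiny_model.eval()
        out = tiny_model(rng.random((1, 3, 32, 32)).astype(np.float32))
        np.testing.assert_array_equal(out.data, np.full((1, 1, 32, 32), 0.5))

    def test_eval_forward_deterministic(self, tiny_model, rng):
        x = rng.random((1, 3, 32, 32)).astype(np.float32)
        tiny_model.eval()
        with no_grad():
            a = tiny_model(x).data
            b = tiny_model(x).data
        np.testing.assert_array_equal(a, b)

    def test_decoder_aligns_odd_skip_sizes(self, rng):
        from hybridseg.model import DecoderBlock

        block = DecoderBlock(8, 4, 4, 2, rng)
        x = Tensor(rng.standard_normal((1, 8, 16, 16)).astype(np.float32))
        skip = Tensor(rng.standard_normal((1, 4, 33, 33)).astype(np.float32))
        out = block(x, skip)  # 32x32 upsample resampled onto the 33x33 grid
        assert out.shape == (1, 4, 33, 33)


class TestAblation:
    def test_transformer_disabled_is_pure_cnn_path(self, rng):
        cfg = ArchitectureConfig(base_channels=4, input_size=32, use_transformer=False)
        model = HybridUNet(cfg, np.random.default_rng(7))
        assert count_parameters(model)["transformer_part"] == 0
        model.eval()
        out = model(rng.random((1, 3, 32, 32)).astype(np.float32), record=True)
        assert out.shape == (1, 1, 32, 32)
        assert "tokens" not in model.last_trace

    def test_hybrid_and_unet_differ_only_in_bottleneck_names(self):
        hybrid = HybridUNet(
            ArchitectureConfig(base_channels=4, input_size=32), np.random.default_rng(0)
        )
        plain = HybridUNet(
            ArchitectureConfig(base_channels=4, input_size=32, use_transformer=False),
            np.random.default_rng(0),
        )
        h_names = {n for n, _ in hybrid.named_parameters()}
        p_names = {n for n, _ in plain.named_parameters()}
        assert p_names < h_names
        extra = h_names - p_names
        assert all(n.startswith("bottleneck.") for n in extra)


class TestParameterAccounting:
    def test_total_is_sum_of_layer_formula(self, tiny_model):
        """Every convolution contributes exactly conv_param_count of its spec."""
        conv_total = 0
        for _, mod in tiny_model.named_modules():
            if isinstance(mod, nn.Conv2d):
                conv_total += conv_param_count(
                    ConvSpec(mod.in_channels, mod.out_channels, mod.kernel_size,
                             bias=mod.bias is not None)
                )
        by_hand = sum(
            p.data.size for n, p in tiny_model.named_parameters()
            if ".conv" in n or n.startswith("head") or ".proj." in n
        )
        assert conv_total == by_hand
        counts = count_parameters(tiny_model)
        assert counts["total"] == sum(p.data.size for p in tiny_model.parameters())
        assert counts["total"] == counts["transformer_part"] + counts["cnn_part"]

    def test_count_invariant_to_input(self, tiny_model, rng):
        before = count_parameters(tiny_model)
        tiny_model(rng.random((2, 3, 32, 32)).astype(np.float32))
        assert count_parameters(tiny_model) == before

    def test_output_head_is_33_parameters(self, tiny_model):
        cfg = ArchitectureConfig()  # default base 32
        model_head = conv_param_count(ConvSpec(cfg.base_channels, 1, 1, bias=True))
        assert model_head == 33


class TestBinarize:
    def test_threshold_rule_and_tie_to_foreground(self):
        p = np.array([0.6, 0.4, 0.5])
        np.testing.assert_array_equal(binarize(p), [1, 0, 1])

    def test_idempotent(self, rng):
        p = rng.random(100)
        once = binarize(p)
        np.testing.assert_array_equal(binarize(once), once)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.array([0.5]), threshold=1.5)


class TestConfigValidation:
    def test_indivisible_input_size(self):
        with pytest.raises(ConfigurationError):
            ArchitectureConfig(input_size=250)

    def test_inconsistent_bottleneck(self):
        with pytest.raises(ConfigurationError):
            ArchitectureConfig(bottleneck_channels=300)

    def test_heads_must_divide_embed_dim(self):
        with pytest.raises(ConfigurationError):
            ArchitectureConfig(base_channels=4, input_size=32, attention_heads=7)

    def test_roundtrip_through_dict(self):
        cfg = ArchitectureConfig(base_channels=8, input_size=64)
        assert ArchitectureConfig.from_dict(cfg.to_dict()) == cfg
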