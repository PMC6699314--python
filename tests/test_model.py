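"""Architecture wiring, parameter accounting, forward contracts, gradients."""

import numpy as np
import pytest

from cardseg.dataio import GrayImage
from cardseg.errors import ConfigurationError, ContractError
from cardseg.losses import batch_loss_and_grad
from cardseg.model import (
    NetSpec,
    ResidualBlock,
    build_network,
    build_unet_baseline,
    count_parameters,
    load_checkpoint,
    predict,
    probs_to_labels,
    save_checkpoint,
)


def residual_block_param_count(c_in, c_out, bn=True):
    """Closed-form count: 3x3 + 3x3 + 1x1 kernels (+ BN affine pairs)."""
    kernels = 9 * c_in * c_out + 9 * c_out * c_out + c_in * c_out
    return kernels + (3 * 2 * c_out if bn else 3 * c_out)  # biases when no BN


class TestResidualBlock:
    def test_first_block_kernel_count_is_5424_plus_bn(self):
        rng = np.random.default_rng(0)
        block = ResidualBlock(1, 24, rng, bn=True)
        conv_params = sum(p.size for p in block.parameters() if p.name.endswith(".w"))
        assert conv_params == 9 * 1 * 24 + 9 * 24 * 24 + 1 * 24 == 5424
        bn_params = sum(p.size for p in block.parameters() if "bn" in p.name)
        assert bn_params == 3 * 2 * 24

    @pytest.mark.parametrize("c_in,c_out", [(1, 24), (8, 8), (16, 32)])
    def test_closed_form_count_matches_enumeration(self, c_in, c_out):
        block = ResidualBlock(c_in, c_out, np.random.default_rng(0), bn=True)
        assert sum(p.size for p in block.parameters()) == residual_block_param_count(c_in, c_out)

    def test_spatial_shape_preserved(self, rng):
        block = ResidualBlock(3, 8, np.random.default_rng(0))
        x = rng.random((2, 12, 10, 3)).astype(np.float32)
        assert block.forward(x, train=True).shape == (2, 12, 10, 8)

    def test_zero_main_path_reduces_to_shortcut(self, rng):
        # with the two 3x3 conv kernels zeroed (and BN disabled) the block
        # must compute ReLU(shortcut(x))
        block = ResidualBlock(4, 4, np.random.default_rng(0), bn=False)
        block.conv1.w.value[...] = 0.0
        block.conv1.b.value[...] = 0.0
        block.conv2.w.value[...] = 0.0
        block.conv2.b.value[...] = 0.0
        x = rng.random((1, 6, 6, 4)).astype(np.float32)
        out = block.forward(x)
        shortcut = block.conv_sc.forward(x)
        np.testing.assert_allclose(out, np.maximum(shortcut, 0.0), atol=1e-6)


class TestParameterCounts:
    def test_default_spec_matches_published_total_within_5pct(self):
        net = build_network()
        total = count_parameters(net)
        assert abs(total / 1e6 - 4.4) / 4.4 <= 0.05

    def test_total_is_sum_over_blocks_and_heads(self):
        net = build_network(NetSpec(base_width=8, levels=2, rows=32, cols=32))
        by_parts = sum(p.size for p in net.parameters())
        assert count_parameters(net) == by_parts

    def test_head_conv_count(self):
        net = build_network()
        head = net.head
        assert sum(p.size for p in head.parameters()) == 24 * 4 + 4

    def test_tiny_network_hand_count(self):
        # base 1, 1 level, K=2, no BN: enumerate by hand
        spec = NetSpec(rows=8, cols=8, base_width=1, levels=1, growth=2, n_classes=2, batch_norm=False)
        net = build_network(spec)
        expected = (
            residual_block_param_count(1, 1, bn=False)  # encoder
            + residual_block_param_count(1, 2, bn=False)  # bottleneck
            + (2 * 2 * 2 * 1 + 1)  # 2x2 transposed conv 2->1 + bias
            + residual_block_param_count(2, 1, bn=False)  # decoder (concat 1+1)
            + (1 * 2 + 2)  # 1x1 head to 2 classes
        )
        assert count_parameters(net) == expected

    def test_doubling_base_width_roughly_quadruples_parameters(self):
        small = count_parameters(build_network(NetSpec(base_width=8, levels=3)))
        big = count_parameters(build_network(NetSpec(base_width=16, levels=3)))
        assert 3.5 < big / small < 4.5

    def test_unet64_baseline_is_order_30_million(self):
        total = count_parameters(build_unet_baseline(64))
        assert 1e7 < total < 6e7

    def test_unet_minimal_hand_count(self):
        net = build_unet_baseline(1, n_classes=2, bn=False, rows=16, cols=16, seed=0)

        def double(c_in, c_out):
            return 9 * c_in * c_out + c_out + 9 * c_out * c_out + c_out

        expected = (
            double(1, 1) + double(1, 2) + double(2, 4) + double(4, 8)  # encoder
            + double(8, 16)  # bottleneck
            + (4 * 16 * 8 + 8) + double(16, 8)
            + (4 * 8 * 4 + 4) + double(8, 4)
            + (4 * 4 * 2 + 2) + double(4, 2)
            + (4 * 2 * 1 + 1) + double(2, 1)
            + (1 * 2 + 2)
        )
        assert count_parameters(net) == expected


class TestForwardContract:
    def test_output_shape_and_softmax_normalization(self, rng):
        spec = NetSpec(rows=32, cols=32, base_width=4, levels=2)
        net = build_network(spec, seed=1)
        x = rng.random((2, 32, 32, 1)).astype(np.float32)
        probs = net.forward(x, train=False)
        assert probs.shape == (2, 32, 32, 4)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_bottleneck_spatial_size_for_default_grid(self):
        # 160x128 halves four times to 10x8
        net = build_network()
        x = np.zeros((1, 160, 128, 1), dtype=np.float32)
        skips = []
        h = x
        for blk, pool in zip(net.enc_blocks, net.pools):
            h = pool.forward(blk.forward(h))
        assert h.shape[1:3] == (10, 8)

    def test_eval_forward_is_deterministic(self, rng):
        spec = NetSpec(rows=16, cols=16, base_width=2, levels=2)
        net = build_network(spec, seed=3)
        x = rng.random((1, 16, 16, 1)).astype(np.float32)
        a = net.forward(x, train=False)
        b = net.forward(x, train=False)
        np.testing.assert_array_equal(a, b)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ConfigurationError):
            NetSpec(rows=100, cols=128, levels=4)

    def test_wrong_input_size_rejected(self, rng):
        net = build_network(NetSpec(rows=16, cols=16, base_width=2, levels=1))
        with pytest.raises(ContractError):
            net.forward(rng.random((1, 8, 8, 1)).astype(np.float32))


class TestPredict:
    def test_uniform_probabilities_break_ties_to_background(self):
        probs = np.full((1, 4, 4, 4), 0.25)
        np.testing.assert_array_equal(probs_to_labels(probs), 1)

    def test_certain_class_wins(self):
        probs = np.zeros((1, 2, 2, 4))
        probs[..., 3] = 1.0
        np.testing.assert_array_equal(probs_to_labels(probs), 4)

    def test_predict_returns_valid_label_map(self, rng):
        spec = NetSpec(rows=16, cols=16, base_width=2, levels=2)
        net = build_network(spec, seed=0)
        image = GrayImage(rng.random((16, 16)), "float")
        label = predict(net, image)
        assert label.shape == (16, 16)
        assert np.isin(label.labels, (1, 2, 3, 4)).all()


class TestGradients:
    @pytest.mark.usefixtures("float64_engine")
    def test_full_network_gradients_match_finite_differences(self):
        spec = NetSpec(rows=8, cols=8, base_width=2, levels=1, dropout=0.0)
        net = build_network(spec, seed=1)
        rng = np.random.default_rng(0)
        x = rng.random((2, 8, 8, 1))
        y = rng.integers(1, 5, (2, 8, 8))

        def loss_at():
            probs = net.forward(x, train=True)
            return batch_loss_and_grad(probs, y, "igd")[0]

        probs = net.forward(x, train=True)
        _, dprobs = batch_loss_and_grad(probs, y, "igd")
        for p in net.parameters():
            p.grad[...] = 0.0
        net.backward(dprobs)

        idx_rng = np.random.default_rng(7)
        h = 1e-6
        for p in net.parameters():
            for _ in range(2):
                idx = tuple(idx_rng.integers(0, s) for s in p.value.shape)
                old = p.value[idx]
                p.value[idx] = old + h
                lp = loss_at()
                p.value[idx] = old - h
                lm = loss_at()
                p.value[idx] = old
                fd = (lp - lm) / (2 * h)
                assert fd == pytest.approx(p.grad[idx], rel=1e-4, abs=1e-9), p.name


class TestCheckpoints:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        spec = NetSpec(rows=16, cols=16, base_width=2, levels=2)
        net = build_network(spec, seed=5)
        x = rng.random((1, 16, 16, 1)).astype(np.float32)
        before = net.forward(x, train=False)
        save_checkpoint(net, tmp_path / "model.npz", extra={"note": "test"})
        restored, extra = load_checkpoint(tmp_path / "model.npz")
        assert extra == {"note": "test"}
        np.testing.assert_array_equal(restored.forward(x, train=False), before)
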